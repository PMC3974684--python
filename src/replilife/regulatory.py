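"""Promoter-binding overlap analysis for ChIP-seq peak calls.

Given called binding peaks for transcription factors (here typically
DAF-16/FoxO, PHA-4/FoxA and MDL-1/Mad) and a table of gene transcription
start sites, this module:

* profiles peak midpoints relative to the nearest TSS (strand-aware,
  upstream negative) — the basis for the empirical promoter window;
* assigns target genes by requiring a peak midpoint within a window of
  the TSS, default [-700, +100] bp inclusive;
* scans peak sequences for E-boxes (CANNTG, the Myc-family consensus;
  the motif class is its own reverse complement, so one strand suffices);
* computes three-way target-set Venn region counts;
* scores GO-term enrichment of a bound-gene set against the genome with
  the Pearson chi-squared test (1 df, no continuity correction);
* measures how much of a peak is covered by the union of another
  factor's peaks (the ">= 75% overlapped" criterion).

Coordinates are 0-based half-open (BED dialect) throughout; a TSS is a
single 0-based coordinate.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import chi2_contingency

from .errors import (
    AlphabetError,
    MissingSequenceError,
    NoGeneOnChromError,
    NotInUniverseError,
)

__all__ = [
    "Peak",
    "Gene",
    "VennCounts",
    "EnrichmentRow",
    "DEFAULT_WINDOW",
    "peak_midpoint",
    "tss_offset_profile",
    "assign_targets",
    "scan_ebox",
    "ebox_fraction",
    "venn3",
    "chisq_enrichment",
    "peak_overlap_fraction",
]

DEFAULT_WINDOW: tuple[int, int] = (-700, 100)


@dataclass(frozen=True)
class Peak:
    """A called binding interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    factor: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class Gene:
    """A gene reduced to its TSS, strand, and GO annotation."""

    id: str
    chrom: str
    tss: int
    strand: str
    go_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class VennCounts:
    """The seven region counts of a three-set Venn diagram plus the rest.

    Field names give the exclusive membership pattern (a = in A only,
    ab = in A and B but not C, ...).
    """

    a: int
    b: int
    c: int
    ab: int
    ac: int
    bc: int
    abc: int
    outside: int

    def total(self) -> int:
        return self.a + self.b + self.c + self.ab + self.ac + self.bc + self.abc + self.outside


@dataclass(frozen=True)
class EnrichmentRow:
    """One GO term's 2x2 enrichment of a bound-gene set vs the genome."""

    term: str
    k_in: int      # bound genes carrying the term
    n_in: int      # bound genes
    k_out: int     # unbound genes carrying the term
    n_out: int     # unbound genes
    chi2: float
    p: float
    fold: float
    degenerate: bool = False


# ---------------------------------------------------------------------------


def peak_midpoint(peak: Peak) -> int:
    """Coordinate of the middle base of a half-open interval.

    Even-length peaks take the left-of-centre base: floor((start+end-1)/2).
    """
    return (peak.start + peak.end - 1) // 2


def _signed_offset(midpoint: int, gene: Gene) -> int:
    """Strand-aware offset of a position from a gene's TSS (upstream < 0)."""
    return midpoint - gene.tss if gene.strand == "+" else gene.tss - midpoint


def tss_offset_profile(
    peaks: list[Peak],
    genes: list[Gene],
    bin_width: int = 50,
    span: tuple[int, int] = (-2000, 2000),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of peak-midpoint offsets to the nearest TSS.

    For every peak, the nearest TSS on the same chromosome is found and
    the strand-aware signed offset recorded; offsets are binned on
    ``span`` with ``bin_width`` bp bins.  Returns (bin_edges, counts).
    Chromosomes holding peaks but no genes are skipped with a warning.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    sorted_tss = {
        c: (np.array([g.tss for g in gl]), gl)
        for c, gl in ((c, sorted(gl, key=lambda g: g.tss)) for c, gl in by_chrom.items())
    }

    offsets = []
    missing: set[str] = set()
    for p in peaks:
        if p.chrom not in sorted_tss:
            missing.add(p.chrom)
            continue
        tss_arr, gene_list = sorted_tss[p.chrom]
        mid = peak_midpoint(p)
        j = int(np.argmin(np.abs(tss_arr - mid)))
        offsets.append(_signed_offset(mid, gene_list[j]))
    for c in sorted(missing):
        warnings.warn(f"no gene on chromosome {c}; its peaks were skipped",
                      category=UserWarning, stacklevel=2)
    edges = np.arange(span[0], span[1] + bin_width, bin_width)
    counts, _ = np.histogram(offsets, bins=edges)
    return edges, counts


def assign_targets(
    peaks: list[Peak],
    genes: list[Gene],
    window: tuple[int, int] = DEFAULT_WINDOW,
    nearest_only: bool = False,
) -> dict[str, set[str]]:
    """Map each factor to the set of genes it targets.

    A gene is a target of a factor iff some peak of that factor has its
    midpoint at a strand-aware offset within ``window`` of the gene's TSS
    (inclusive at both ends; default [-700, +100]).  A peak may target
    several flanking genes and a gene may be hit by several peaks; with
    ``nearest_only`` each peak is credited only to its nearest in-window
    TSS.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window lower bound must be below upper bound")
    genes_by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    targets: dict[str, set[str]] = {}
    for p in peaks:
        hits: list[tuple[int, str]] = []
        mid = peak_midpoint(p)
        for g in genes_by_chrom.get(p.chrom, ()):  # genomes here are small
            off = _signed_offset(mid, g)
            if lo <= off <= hi:
                hits.append((abs(off), g.id))
        if not hits:
            continue
        bucket = targets.setdefault(p.factor, set())
        if nearest_only:
            bucket.add(min(hits)[1])
        else:
            bucket.update(gid for _, gid in hits)
    return targets


_EBOX = re.compile(r"(?=CA[ACGTN]{2}TG)")
_VALID = re.compile(r"[ACGTN]*\Z")


def scan_ebox(sequence: str) -> int:
    """Count E-box (CANNTG) matches in a DNA string, overlaps included.

    One strand suffices: the reverse complement of any CANNTG is again a
    CANNTG.  Lowercase input is accepted; anything outside {A,C,G,T,N}
    raises :class:`AlphabetError`.
    """
    seq = sequence.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise AlphabetError(f"invalid characters in sequence: {bad}")
    return sum(1 for _ in _EBOX.finditer(seq))


def ebox_fraction(
    peaks: list[Peak], sequences: dict[str, str]
) -> tuple[float, float]:
    """Fraction of peaks whose sequence contains at least one E-box.

    ``sequences`` is keyed by peak name.  Returns ``(fraction, percent)``
    where ``percent`` is the fraction expressed to one decimal with
    half-away-from-zero rounding (the convention of reported values).
    """
    if not peaks:
        return 0.0, 0.0
    n_hit = 0
    for p in peaks:
        seq = sequences.get(p.name)
        if seq is None:
            raise MissingSequenceError(f"no sequence for peak {p.name!r}")
        if scan_ebox(seq) > 0:
            n_hit += 1
    frac = n_hit / len(peaks)
    pct = float(Decimal(repr(100.0 * frac)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return frac, pct


def venn3(
    set_a: set, set_b: set, set_c: set, universe: set
) -> VennCounts:
    """Exclusive region counts of three sets within a universe."""
    for name, s in (("A", set_a), ("B", set_b), ("C", set_c)):
        extra = s - universe
        if extra:
            raise NotInUniverseError(
                f"set {name} has {len(extra)} element(s) outside the universe"
            )
    abc = set_a & set_b & set_c
    ab = (set_a & set_b) - abc
    ac = (set_a & set_c) - abc
    bc = (set_b & set_c) - abc
    a = set_a - set_b - set_c
    b = set_b - set_a - set_c
    c = set_c - set_a - set_b
    outside = universe - set_a - set_b - set_c
    return VennCounts(
        a=len(a), b=len(b), c=len(c),
        ab=len(ab), ac=len(ac), bc=len(bc),
        abc=len(abc), outside=len(outside),
    )


def chisq_enrichment(
    target_genes: set[str],
    genes: list[Gene],
    terms: list[str] | None = None,
    bh_correct: bool = False,
) -> list[EnrichmentRow]:
    """Per-GO-term chi-squared enrichment of a bound-gene set vs the genome.

    For each term the 2x2 table (in target vs not) x (has term vs not) is
    scored with Pearson chi-squared, 1 df, no continuity correction.  Fold
    enrichment is the term frequency among targets over its genome-wide
    frequency.  Tables with a zero margin are emitted flagged with p = 1.
    Rows come back sorted by p then term.  ``bh_correct`` appends no
    column here; apply Benjamini-Hochberg downstream if desired — raw
    p-values are the reported convention.
    """
    gene_ids = {g.id for g in genes}
    missing = target_genes - gene_ids
    if missing:
        raise NotInUniverseError(
            f"{len(missing)} target gene(s) missing from the gene table"
        )
    if terms is None:
        terms = sorted({t for g in genes for t in g.go_terms})

    n_in = len(target_genes)
    n_out = len(genes) - n_in
    n_tot = len(genes)
    rows: list[EnrichmentRow] = []
    for term in terms:
        k_in = sum(1 for g in genes if g.id in target_genes and term in g.go_terms)
        k_tot = sum(1 for g in genes if term in g.go_terms)
        k_out = k_tot - k_in
        table = np.array([[k_in, n_in - k_in], [k_out, n_out - k_out]], dtype=float)
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = chi2_contingency(table, correction=False)
        genome_freq = k_tot / n_tot if n_tot else 0.0
        fold = (k_in / n_in) / genome_freq if (n_in and genome_freq) else (
            1.0 if k_in == 0 else float("inf")
        )
        rows.append(
            EnrichmentRow(
                term=term, k_in=k_in, n_in=n_in, k_out=k_out, n_out=n_out,
                chi2=float(chi2), p=float(p), fold=float(fold),
                degenerate=bool(degenerate),
            )
        )
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def peak_overlap_fraction(peak: Peak, other_peaks: list[Peak]) -> float:
    """Fraction of a peak's bases covered by the union of other peaks."""
    length = peak.end - peak.start
    segs = sorted(
        (max(o.start, peak.start), min(o.end, peak.end))
        for o in other_peaks
        if o.chrom == peak.chrom and o.start < peak.end and o.end > peak.start
    )
    covered = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in segs:
        if cur_start is None:
            cur_start, cur_end = s, e
        elif s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
    if cur_start is not None:
        covered += cur_end - cur_start
    return covered / length
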