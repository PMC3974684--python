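"""Seeded generators for every input the analysis pipelines consume.

Two families:

* Survival: replica-set mortality tables (wells of ~25 animals, each
  scored once, deaths binomial under a true logit survival curve) and
  traditional per-animal lifespan event lists (inverse-CDF draws from the
  logistic survival curve, optional independent censoring).

* Genomic: a toy genome with genes on a regular TSS grid, binding peaks
  planted inside the promoter window of a chosen fraction of genes (decoy
  peaks kept well clear of every window), peak sequences with E-boxes
  planted in a stated fraction (and scrubbed from everything else, so the
  realised fraction is exact), and a GO annotation with one term enriched
  among the planted targets at a stated fold.

Every generator takes a seed and is deterministic given it.  RNG stream
order for the genome: gene strands -> per-factor target choice -> peak
offsets/jitter -> sequences -> GO assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError
from .regulatory import DEFAULT_WINDOW, Gene, Peak, _EBOX
from .survival import LifespanEvent, MortalityObservation, ObservationSet

__all__ = [
    "ReplicaSetScenario",
    "GenomeScenario",
    "GenomeData",
    "simulate_replica_set",
    "simulate_traditional_lifespan",
    "simulate_genome",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReplicaSetScenario:
    """Study conditions for one simulated replica-set experiment.

    Defaults mirror the bench protocol: 24-well plates scored every other
    day with on average 25 animals per well, and a wild-type-like true
    curve a = 0.4/day, b = 7.2 (LD50 = 18 days).
    """

    true_a: float = 0.4
    true_b: float = 7.2
    n_wells: int = 24
    animals_per_well: int = 25
    schedule: tuple[float, ...] = tuple(range(2, 26, 2))
    condition: str = "sim"
    time_unit: str = "days"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_a <= 0:
            raise ValueError("true_a must be > 0 (declining survival)")
        if self.n_wells < 2:
            raise ValueError("need at least 2 wells")
        if not self.schedule:
            raise ValueError("schedule must be nonempty")

    @property
    def true_ld50(self) -> float:
        return self.true_b / self.true_a


def simulate_replica_set(s: ReplicaSetScenario, exact: bool = False) -> ObservationSet:
    """Draw one replica-set mortality table under a true logit curve.

    Wells take timepoints round-robin over the schedule so every
    timepoint is covered evenly; deaths per well are
    Binomial(animals_per_well, 1 - p(t)).  With ``exact`` the binomial
    draw is replaced by its expectation (fractional counts) — the
    infinite-animal limit, useful for noise-free checks.
    """
    rng = np.random.default_rng(s.seed)
    times = np.array([s.schedule[i % len(s.schedule)] for i in range(s.n_wells)], float)
    p_surv = 1.0 / (1.0 + np.exp(np.clip(s.true_a * times - s.true_b, -700, 700)))
    if exact:
        dead = s.animals_per_well * (1.0 - p_surv)
    else:
        dead = rng.binomial(s.animals_per_well, 1.0 - p_surv).astype(float)
    alive = s.animals_per_well - dead
    obs = [
        MortalityObservation(float(t), float(a), float(d), s.condition, trial="sim")
        for t, a, d in zip(times, alive, dead)
    ]
    return ObservationSet(obs, time_unit=s.time_unit, condition=s.condition)


def simulate_traditional_lifespan(
    n: int,
    true_a: float,
    true_b: float,
    censor_rate: float = 0.0,
    seed: int | None = None,
    condition: str = "sim",
) -> list[LifespanEvent]:
    """Per-animal death days drawn from the logistic survival curve.

    Inverse-CDF: with U ~ Uniform(0,1), T = (b - logit(U))/a has survival
    function 1/(1+exp(a*t-b)); draws are truncated at 0 (the curve puts
    a small mass at negative times when b/a is small relative to 1/a).
    Censoring is independent: with probability ``censor_rate`` an animal
    is instead censored at a uniform time before its death.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t = np.maximum((true_b - np.log(u / (1.0 - u))) / true_a, 0.0)
    censored = rng.uniform(size=n) < censor_rate
    days = np.where(censored, rng.uniform(size=n) * t, t)
    return [
        LifespanEvent(day=float(d), censored=bool(c), condition=condition)
        for d, c in zip(days, censored)
    ]


@dataclass(frozen=True)
class GenomeScenario:
    """Study conditions for the toy regulatory genome.

    Genes sit on a regular TSS grid (spacing = chrom_length / (genes per
    chromosome + 1)); planted peaks fall strand-aware inside
    ``offset_range`` of their gene's TSS, decoys at least 1500 bp from
    every TSS.  ``planted_ebox_fraction`` of all peak sequences receive
    one E-box; all other sequences are scrubbed E-box-free so the
    realised fraction is exact.  One GO term (the first in the
    vocabulary) is enriched among the first factor's planted targets at
    ``enriched_fold`` times the background term probability.
    """

    n_chroms: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 1000
    n_peaks_per_factor: int = 600
    factors: tuple[str, ...] = ("MDL-1",)
    planted_target_fraction: float = 0.5
    offset_range: tuple[int, int] = DEFAULT_WINDOW
    peak_width: int = 201
    planted_ebox_fraction: float = 0.5
    n_go_terms: int = 20
    background_term_prob: float = 0.08
    enriched_fold: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for f in (self.planted_target_fraction, self.planted_ebox_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("planted fractions must lie in [0, 1]")
        if self.n_genes < self.n_chroms:
            raise ValueError("need at least one gene per chromosome")

    @property
    def enriched_term(self) -> str:
        return "GO:0000001"


@dataclass
class GenomeData:
    """Everything the regulatory pipeline consumes, in memory."""

    genes: list[Gene]
    peaks: list[Peak]
    sequences: dict[str, str]
    planted_targets: dict[str, set[str]]  # factor -> planted gene ids


def _scrub_eboxes(seq: np.ndarray) -> np.ndarray:
    """Mutate a base array until it contains no CANNTG occurrence."""
    while True:
        hits = [m.start() for m in _EBOX.finditer("".join(seq))]
        if not hits:
            return seq
        for h in hits:
            seq[h + 1] = "C"  # CANNTG -> CCNNTG, which cannot rematch


def simulate_genome(g: GenomeScenario) -> GenomeData:
    """Generate genes, peaks, peak sequences and GO annotation.

    Raises :class:`CapacityError` when the chromosome is too short to
    separate promoter windows (TSS grid spacing under 4 kb), since decoy
    peaks could then not be kept out of every window.
    """
    rng = np.random.default_rng(g.seed)
    per_chrom = -(-g.n_genes // g.n_chroms)  # ceil
    spacing = g.chrom_length // (per_chrom + 1)
    if spacing < 4000:
        raise CapacityError(
            f"TSS spacing {spacing} bp < 4000; lengthen chromosomes or drop genes"
        )

    genes_plain: list[tuple[str, str, int, str]] = []  # id, chrom, tss, strand
    gid = 0
    for c in range(g.n_chroms):
        chrom = f"chr{c + 1}"
        for i in range(per_chrom):
            if gid >= g.n_genes:
                break
            strand = "+" if rng.uniform() < 0.5 else "-"
            genes_plain.append((f"gene{gid:04d}", chrom, (i + 1) * spacing, strand))
            gid += 1

    half = g.peak_width // 2
    peaks: list[Peak] = []
    planted_targets: dict[str, set[str]] = {}
    pid = 0
    for factor in g.factors:
        n_plant = round(g.planted_target_fraction * g.n_genes)
        chosen = rng.choice(g.n_genes, size=n_plant, replace=False)
        planted_targets[factor] = {genes_plain[i][0] for i in chosen}
        for i in sorted(chosen):
            _, chrom, tss, strand = genes_plain[i]
            off = int(rng.integers(g.offset_range[0], g.offset_range[1] + 1))
            mid = tss + off if strand == "+" else tss - off
            peaks.append(Peak(chrom, mid - half, mid - half + g.peak_width,
                              factor=factor, name=f"peak{pid:05d}"))
            pid += 1
        # decoys midway between TSS grid points, clear of every window
        n_decoy = g.n_peaks_per_factor - n_plant
        if n_decoy < 0:
            raise CapacityError("more planted targets than peaks for factor " + factor)
        for _ in range(n_decoy):
            i = int(rng.integers(len(genes_plain)))
            _, chrom, tss, _ = genes_plain[i]
            jitter = int(rng.integers(-(spacing // 2 - 1500), spacing // 2 - 1500 + 1))
            mid = tss + spacing // 2 + jitter
            peaks.append(Peak(chrom, mid - half, mid - half + g.peak_width,
                              factor=factor, name=f"peak{pid:05d}"))
            pid += 1

    # sequences: E-box-free background, then plant into a chosen subset
    sequences: dict[str, str] = {}
    n_ebox = round(g.planted_ebox_fraction * len(peaks))
    with_ebox = set(rng.choice(len(peaks), size=n_ebox, replace=False).tolist())
    for k, p in enumerate(peaks):
        seq = _scrub_eboxes(rng.choice(_BASES, size=p.end - p.start))
        if k in with_ebox:
            pos = int(rng.integers(0, len(seq) - 6 + 1))
            core = rng.choice(_BASES, size=2)
            seq[pos:pos + 6] = ["C", "A", core[0], core[1], "T", "G"]
        sequences[p.name] = "".join(seq)

    # GO annotation: background iid, one term enriched among planted targets
    terms = [f"GO:{i + 1:07d}" for i in range(g.n_go_terms)]
    enriched = planted_targets.get(g.factors[0], set())
    p_enriched = min(1.0, g.enriched_fold * g.background_term_prob)
    genes: list[Gene] = []
    for gid_, chrom, tss, strand in genes_plain:
        carried = set()
        for j, term in enumerate(terms):
            p_term = (
                p_enriched if (j == 0 and gid_ in enriched) else g.background_term_prob
            )
            if rng.uniform() < p_term:
                carried.add(term)
        genes.append(Gene(gid_, chrom, tss, strand, frozenset(carried)))

    return GenomeData(genes=genes, peaks=peaks, sequences=sequences,
                      planted_targets=planted_targets)
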