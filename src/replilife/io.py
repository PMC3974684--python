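"""Readers and writers for the package's plain-text dialects.

Formats:

* Mortality TSV — ``condition  trial  well_id  timepoint  n_alive  n_dead``
  (header required, UTF-8, '.' decimal); one row per scored well.
* Lifespan event TSV — ``condition  animal_id  day  censored`` (0/1).
* Peaks — BED with a factor column: ``chrom  start  end  factor  [name]``
  (0-based half-open; '#' comments and blank lines tolerated).
* Gene table — TSV ``id  chrom  tss  strand`` (0-based TSS), or a minimal
  GFF3 restricted to ``gene`` features (TSS derived from the stranded
  5' end, converted to 0-based).
* Peak sequences — FASTA keyed by peak name (Biopython-backed).
* GO annotation — two-column TSV ``gene_id  term_id``.

Malformed rows are reported with 1-based line numbers in a SchemaError.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, SchemaError
from .regulatory import Gene, Peak
from .survival import LifespanEvent, MortalityObservation, ObservationSet

SCHEMA_VERSION = "1.0"

MORTALITY_COLUMNS = ["condition", "trial", "well_id", "timepoint", "n_alive", "n_dead"]
LIFESPAN_COLUMNS = ["condition", "animal_id", "day", "censored"]
GENE_COLUMNS = ["id", "chrom", "tss", "strand"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_mortality_tsv(
    path: str | Path, time_unit: str = "days"
) -> dict[str, ObservationSet]:
    """Load a mortality table, grouped into one ObservationSet per condition."""
    df = _read_tsv(path, MORTALITY_COLUMNS)
    bad: list[str] = []
    rows: list[tuple[str, MortalityObservation]] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            obs = MortalityObservation(
                timepoint=float(row["timepoint"]),
                n_alive=float(row["n_alive"]),
                n_dead=float(row["n_dead"]),
                condition=row["condition"],
                trial=row["trial"],
            )
        except (ValueError, TypeError) as exc:
            bad.append(f"line {line}: {exc}")
            continue
        rows.append((row["condition"], obs))
    if bad:
        raise SchemaError(f"{path}: " + "; ".join(bad))
    out: dict[str, ObservationSet] = {}
    for cond in dict.fromkeys(c for c, _ in rows):  # preserve file order
        out[cond] = ObservationSet(
            [o for c, o in rows if c == cond], time_unit=time_unit, condition=cond
        )
    return out


def write_mortality_tsv(path: str | Path, sets: Iterable[ObservationSet]) -> None:
    recs = []
    for s in sets:
        for j, o in enumerate(s.observations):
            recs.append((o.condition, o.trial or "t1", f"w{j + 1}",
                         o.timepoint, o.n_alive, o.n_dead))
    pd.DataFrame(recs, columns=MORTALITY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_lifespan_tsv(path: str | Path) -> dict[str, list[LifespanEvent]]:
    """Load per-animal death/censor days, grouped by condition."""
    df = _read_tsv(path, LIFESPAN_COLUMNS)
    bad: list[str] = []
    out: dict[str, list[LifespanEvent]] = {}
    for i, row in df.iterrows():
        line = i + 2
        try:
            if row["censored"] not in ("0", "1"):
                raise ValueError(f"censored must be 0 or 1, got {row['censored']!r}")
            ev = LifespanEvent(
                day=float(row["day"]),
                censored=row["censored"] == "1",
                condition=row["condition"],
            )
        except (ValueError, TypeError) as exc:
            bad.append(f"line {line}: {exc}")
            continue
        out.setdefault(row["condition"], []).append(ev)
    if bad:
        raise SchemaError(f"{path}: " + "; ".join(bad))
    return out


def write_lifespan_tsv(path: str | Path, events: Iterable[LifespanEvent]) -> None:
    recs = [
        (e.condition, f"a{i + 1}", e.day, int(e.censored))
        for i, e in enumerate(events)
    ]
    pd.DataFrame(recs, columns=LIFESPAN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bed_peaks(path: str | Path) -> list[Peak]:
    """Read BED3+factor(+name) peak intervals (0-based half-open)."""
    peaks: list[Peak] = []
    bad: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                bad.append(f"line {lineno}: expected >= 4 tab-separated fields")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
                name = fields[4] if len(fields) > 4 else f"{fields[0]}:{start}-{end}"
                peaks.append(Peak(fields[0], start, end, factor=fields[3], name=name))
            except ValueError as exc:
                bad.append(f"line {lineno}: {exc}")
    if bad:
        raise SchemaError(f"{path}: " + "; ".join(bad))
    return peaks


def write_bed_peaks(path: str | Path, peaks: Iterable[Peak]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.factor}\t{p.name}\n")


def read_gene_table(path: str | Path) -> list[Gene]:
    """Read genes from the 4-column TSV dialect or a minimal GFF3.

    GFF3 (by .gff/.gff3 extension): only ``gene`` features are used; the
    TSS is the stranded 5' end converted to 0-based, and the ID comes
    from the ``ID=`` attribute.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3_genes(path)
    df = _read_tsv(path, GENE_COLUMNS)
    genes: list[Gene] = []
    bad: list[str] = []
    for i, row in df.iterrows():
        try:
            genes.append(Gene(row["id"], row["chrom"], int(row["tss"]), row["strand"]))
        except (ValueError, TypeError) as exc:
            bad.append(f"line {i + 2}: {exc}")
    if bad:
        raise SchemaError(f"{path}: " + "; ".join(bad))
    return genes


def _read_gff3_genes(path: Path) -> list[Gene]:
    genes: list[Gene] = []
    bad: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                bad.append(f"line {lineno}: expected 9 GFF3 fields")
                continue
            if fields[2] != "gene":
                continue
            try:
                start1, end1, strand = int(fields[3]), int(fields[4]), fields[6]
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID", f"{fields[0]}:{start1}-{end1}")
                tss = start1 - 1 if strand == "+" else end1 - 1
                genes.append(Gene(gid, fields[0], tss, strand))
            except (ValueError, KeyError) as exc:
                bad.append(f"line {lineno}: {exc}")
    if bad:
        raise SchemaError(f"{path}: " + "; ".join(bad))
    return genes


def write_gene_table(path: str | Path, genes: Iterable[Gene]) -> None:
    pd.DataFrame(
        [(g.id, g.chrom, g.tss, g.strand) for g in genes], columns=GENE_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an id -> uppercase sequence mapping."""
    try:
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_go_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column gene -> GO-term annotation (no header required)."""
    mapping: dict[str, set[str]] = {}
    bad: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                bad.append(f"line {lineno}: expected gene_id<TAB>term_id")
                continue
            if fields[0] == "gene_id":  # tolerated header
                continue
            mapping.setdefault(fields[0], set()).add(fields[1])
    if bad:
        raise SchemaError(f"{path}: " + "; ".join(bad))
    return mapping


def write_go_tsv(path: str | Path, genes: Iterable[Gene]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tterm_id\n")
        for g in genes:
            for term in sorted(g.go_terms):
                fh.write(f"{g.id}\t{term}\n")


def attach_go(genes: list[Gene], mapping: dict[str, set[str]]) -> list[Gene]:
    """Return genes with GO terms merged in from an annotation mapping."""
    return [
        Gene(g.id, g.chrom, g.tss, g.strand, frozenset(mapping.get(g.id, set())))
        for g in genes
    ]


def report(results: dict, path: str | Path, fmt: str = "json") -> None:
    """Write a result record with stable field ordering.

    JSON carries a ``schema_version``; TSV flattens one level of nesting
    into ``key.subkey`` columns.
    """
    if fmt == "json":
        payload = {"schema_version": SCHEMA_VERSION, **results}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "tsv":
        flat: dict[str, object] = {}
        for k, v in results.items():
            if isinstance(v, dict):
                for kk, vv in v.items():
                    flat[f"{k}.{kk}"] = vv
            else:
                flat[k] = v
        pd.DataFrame([flat]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
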