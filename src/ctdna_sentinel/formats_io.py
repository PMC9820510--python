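"""Readers and writers for the external formats the pipeline touches.

Coordinates follow the usual conventions: BED is 0-based half-open on disk
and internally; VCF is emitted 1-based. Percent columns in the packaged
table fixtures are stored as printed (percent scale) and converted to
fractions on load.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True, slots=True)
class PanelRegion:
    """A capture-panel target region (BED semantics: 0-based half-open)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"region start must be < end, got {self.start} >= {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True, slots=True)
class AnnotationRecord:
    """Database-membership flags for one variant key."""

    chrom: str | None
    pos: int | None  # 1-based
    ref: str | None
    alt: str | None
    in_cosmic: bool = False
    in_tcga_bc: bool = False
    in_tcga_all: bool = False
    exonic: bool = False
    gene: str = ""


_NULL_RECORD = AnnotationRecord(None, None, None, None)


class AnnotationIndex:
    """Total lookup of annotation flags by (chrom, pos, ref, alt).

    Absent keys return an all-false record, so every query answers.
    """

    def __init__(self, records: Iterable[AnnotationRecord] = ()) -> None:
        self._by_key: dict[tuple, AnnotationRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: AnnotationRecord) -> None:
        key = (rec.chrom, rec.pos, rec.ref, rec.alt)
        prev = self._by_key.get(key)
        if prev is not None and prev != rec:
            raise ParseError(f"conflicting annotation rows for key {key}")
        self._by_key[key] = rec

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> AnnotationRecord:
        return self._by_key.get((chrom, pos, ref, alt), _NULL_RECORD)

    def __len__(self) -> int:
        return len(self._by_key)


def read_panel_bed(path: str | Path) -> list[PanelRegion]:
    """Parse a BED file into panel regions, kept in file order."""
    regions: list[PanelRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            label = fields[3] if len(fields) > 3 else ""
            try:
                regions.append(PanelRegion(fields[0], start, end, label))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_panel_bed(regions: Iterable[PanelRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_annotation_db(path: str | Path) -> AnnotationIndex:
    """Load a TSV annotation database (chrom, pos, ref, alt, flag columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"annotation DB missing columns: {sorted(missing)}")
    index = AnnotationIndex()
    for row in df.itertuples(index=False):
        index.add(
            AnnotationRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                in_cosmic=bool(getattr(row, "in_cosmic", False)),
                in_tcga_bc=bool(getattr(row, "in_tcga_bc", False)),
                in_tcga_all=bool(getattr(row, "in_tcga_all", False)),
                exonic=bool(getattr(row, "exonic", False)),
                gene=str(getattr(row, "gene", "")),
            )
        )
    return index


def _yn(value: str) -> bool:
    return str(value).strip().upper() == "Y"


def _pct_to_fraction(value) -> float | None:
    text = str(value).strip()
    if text in {"-", "", "nan", "NA"}:
        return None
    return float(text) / 100.0


def _infer_variant_class(nucleotide_change: str, aa_change: str) -> str:
    if "splice" in aa_change.lower():
        return "splice"
    lowered = nucleotide_change.lower()
    if "del" in lowered or "ins" in lowered or "dup" in lowered:
        return "indel"
    return "substitution"


def read_variant_table(path: str | Path, dialect: str):
    """Read a variant list.

    dialect "vcf": minimal VCF 4.2 via cyvcf2, returning a list of Variant
    with 1-based positions (records with ALT "." are skipped).
    dialect "table2"/"table3": the packaged tumor-plasma / plasma-only
    fixture dialects, returned as a DataFrame with VAF percent columns
    converted to fractions and Y/N flags converted to booleans.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "table2":
        df = pd.read_csv(path, sep="\t", dtype=str)
        df["tumor_vaf"] = df["tumor_vaf_pct"].map(_pct_to_fraction)
        df["plasma_vaf"] = df["plasma_vaf_pct"].map(_pct_to_fraction)
        df["caller_detected"] = df["caller_detected"].map(_yn)
        df["manually_detected"] = df["manually_detected"].map(_yn)
        df["variant_class"] = [
            _infer_variant_class(n, a)
            for n, a in zip(df["nucleotide_change"], df["aa_change"])
        ]
        return df
    if dialect == "table3":
        df = pd.read_csv(path, sep="\t", dtype=str)
        df["vaf"] = df["vaf_pct"].map(_pct_to_fraction)
        df["in_databases"] = df["in_databases"].map(_yn)
        df["tumor_sequenced"] = df["tumor_sequenced"].map(_yn)
        # "-" (tumor outcome not reported) is carried as None, not False
        df["any_mutation_in_tumor"] = [
            None if str(v).strip() == "-" else _yn(v)
            for v in df["any_mutation_in_tumor"]
        ]
        df["variant_class"] = [
            _infer_variant_class(n, a)
            for n, a in zip(df["nucleotide_change"], df["aa_change"])
        ]
        return df
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_vcf(path: str | Path):
    from cyvcf2 import VCF

    from .candidate_calling import Variant

    variants: list[Variant] = []
    vcf = VCF(str(path))
    for rec in vcf:
        if not rec.ALT:
            continue  # ALT "." — skipped
        vaf = rec.INFO.get("VAF")
        for alt in rec.ALT:
            variants.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=str(rec.INFO.get("GENE") or ""),
                    sample_id=str(rec.INFO.get("SAMPLE") or ""),
                    vaf=float(vaf) if vaf is not None else None,
                )
            )
    vcf.close()
    return variants


def _chrom_sort_key(chrom: str) -> tuple:
    body = chrom[3:] if chrom.startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    if not body:
        raise ValueError(f"unsortable contig name: {chrom!r}")
    return (1, 0, body)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency (fraction)">
##INFO=<ID=METHOD,Number=1,Type=String,Description="Detection path: caller or rescue">
##INFO=<ID=DUPLEX,Number=1,Type=Integer,Description="Distinct supporting fragment start coordinates">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_detections_vcf(detections, path: str | Path) -> None:
    """Write detections as minimal VCF 4.2 (1-based positions).

    Each detection needs chrom/pos/ref/alt/vaf plus method and
    duplex_coord_count; output round-trips through ``read_variant_table``.
    """
    rows = []
    for det in detections:
        var = getattr(det, "variant", det)
        method = getattr(det, "method", "caller")
        duplex = getattr(det, "duplex_coord_count", 0)
        vaf = getattr(det, "vaf", None)
        if vaf is None:
            vaf = var.vaf
        key = (_chrom_sort_key(var.chrom), var.pos, var.alt)
        info = (
            f"VAF={vaf:.6g};METHOD={method};DUPLEX={duplex}"
            f";GENE={var.gene or '.'};SAMPLE={var.sample_id or '.'}"
        )
        rows.append((key, f"{var.chrom}\t{var.pos}\t.\t{var.ref}\t{var.alt}\t.\tPASS\t{info}"))
    rows.sort(key=lambda item: item[0])
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for _, line in rows:
            fh.write(line + "\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet (CSV or TSV inferred from extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError("sample sheet requires a sample_id column")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"duplicate sample_id in sheet: {dupes}")
    return df


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed from the published cohort tables)

def _fixture_path(name: str) -> Path:
    return Path(importlib.resources.files("ctdna_sentinel") / "fixtures" / name)


def load_panel_fixture() -> list[PanelRegion]:
    """The 33-gene breast-cancer capture panel."""
    return read_panel_bed(_fixture_path("panel_33genes.bed"))


def load_table2_fixture() -> pd.DataFrame:
    """Tumor mutations and their plasma detection status (61 rows, 40 samples)."""
    df = read_variant_table(_fixture_path("table2_tumor_plasma.tsv"), "table2")
    if len(df) != 61 or df["sample"].nunique() != 40:
        raise ParseError(
            "tumor-plasma fixture corrupted: expected 61 rows over 40 samples, "
            f"got {len(df)} rows over {df['sample'].nunique()} samples"
        )
    return df


def load_table3_fixture() -> pd.DataFrame:
    """Plasma-only mutations from the naive pipeline (16 rows, 14 samples)."""
    df = read_variant_table(_fixture_path("table3_plasma_only.tsv"), "table3")
    if len(df) != 16 or df["sample"].nunique() != 14:
        raise ParseError(
            "plasma-only fixture corrupted: expected 16 rows over 14 samples, "
            f"got {len(df)} rows over {df['sample'].nunique()} samples"
        )
    return df


def load_cohort_fixture() -> pd.DataFrame:
    """Per-sample cohort sheet reconstructed to match the published marginals."""
    return read_sample_sheet(_fixture_path("table1_cohort.tsv"))
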