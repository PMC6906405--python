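"""Variant-to-gene mapping, gene-set window filtering and cohort intersection.

An exome analysis targeted to a seed network keeps only the variants lying in
a member gene or within a fixed flanking window (default 20 kbp) of one; when
several cohorts are merged, only variants typed in all of them survive.
Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 20_000


@dataclass(frozen=True)
class VariantKey:
    """Identity of a biallelic variant: chromosome, position, REF, ALT.

    ``id`` is an optional rsID/locus label and does not participate in
    equality — two cohorts calling the same site under different labels still
    intersect.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be 1-based (>= 1)")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")

    def __eq__(self, other) -> bool:
        if not isinstance(other, VariantKey):
            return NotImplemented
        return self.normalized_tuple() == other.normalized_tuple()

    def __hash__(self) -> int:
        return hash(self.normalized_tuple())

    def normalized_tuple(self) -> tuple[str, int, str, str]:
        chrom = self.chromosome.lower().removeprefix("chr")
        return (chrom, self.position, self.ref.upper(), self.alt.upper())

    def label(self) -> str:
        return self.id or f"{self.chromosome}:{self.position}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic span, 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def load_genes(bed_path) -> list[GeneInterval]:
    """Read gene intervals from a BED file (>= 4 columns).

    BED is 0-based half-open; intervals are converted to 1-based inclusive.
    Strand is taken from column 6 when present, else ``unknown``.
    """
    genes: list[GeneInterval] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"{bed_path}: line {lineno}: BED needs >= 4 columns")
            chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start0 >= end0:
                raise ValueError(f"{bed_path}: line {lineno}: empty/negative interval")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "unknown"
            genes.append(
                GeneInterval(gene_id=name, chromosome=chrom,
                             start=start0 + 1, end=end0, strand=strand)
            )
    return genes


def write_genes_bed(genes: Iterable[GeneInterval], path) -> None:
    """Write gene intervals as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            strand = g.strand if g.strand in "+-" else "."
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_variants_to_geneset(
    variants: Sequence[VariantKey],
    genes: Sequence[GeneInterval],
    member_ids: Iterable[str],
    flank: int = DEFAULT_FLANK,
) -> tuple[list[VariantKey], dict[VariantKey, list[str]]]:
    """Keep variants inside a member gene or within ``flank`` bp of one.

    A variant survives iff its position lies in ``[start - flank, end + flank]``
    (both boundaries inclusive, clipped at 1) of at least one gene whose id is
    in ``member_ids``; the flank is applied on both sides regardless of
    strand.  Returns the kept variants (input order) and, per kept variant,
    every matching gene id.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    members = set(member_ids)
    windows: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        if g.gene_id in members:
            windows.setdefault(str(g.chromosome), []).append(
                (max(1, g.start - flank), g.end + flank, g.gene_id)
            )
    kept: list[VariantKey] = []
    assignment: dict[VariantKey, list[str]] = {}
    for v in variants:
        chrom = v.chromosome.lower().removeprefix("chr")
        hits = [
            gid
            for c, spans in windows.items()
            if c.lower().removeprefix("chr") == chrom
            for lo, hi, gid in spans
            if lo <= v.position <= hi
        ]
        if hits:
            kept.append(v)
            assignment[v] = sorted(set(hits))
    return kept, assignment


def normalize_keys(variants: Iterable[VariantKey]) -> set[VariantKey]:
    """Split multi-allelic records into biallelic keys (ALT comma lists)."""
    out: set[VariantKey] = set()
    for v in variants:
        for alt in v.alt.split(","):
            out.add(VariantKey(v.chromosome, v.position, v.ref, alt, v.id))
    return out


def intersect_cohorts(
    variant_key_sets: Sequence[Iterable[VariantKey]],
) -> tuple[set[VariantKey], list[int]]:
    """Variants typed in every cohort, under normalised biallelic keys.

    Chromosome labels are compared with any ``chr`` prefix stripped;
    multi-allelic records are collapsed into biallelic keys first.  Returns
    the common set and, per cohort, the number of its variants excluded.
    """
    if len(variant_key_sets) < 2:
        raise ValueError("need at least two cohorts to intersect")
    normalized = [normalize_keys(s) for s in variant_key_sets]
    common = set.intersection(*normalized)
    excluded = [len(s) - len(s & common) for s in normalized]
    return common, excluded


def variants_in_table(df: pd.DataFrame) -> list[VariantKey]:
    """Build keys from a site table with CHR/BP/REF/ALT (and optional ID)."""
    cols = {c.upper(): c for c in df.columns}
    need = ["CHR", "BP", "REF", "ALT"]
    missing = [c for c in need if c not in cols]
    if missing:
        raise ValueError(f"site table lacks columns: {missing}")
    ids = df[cols["ID"]] if "ID" in cols else [None] * len(df)
    return [
        VariantKey(str(c), int(p), str(r), str(a), i if i is None or pd.notna(i) else None)
        for c, p, r, a, i in zip(
            df[cols["CHR"]], df[cols["BP"]], df[cols["REF"]], df[cols["ALT"]], ids
        )
    ]
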