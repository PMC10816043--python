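"""Variant-level I/O: multi-sample genotypes (VCF) and annotation tables.

Genotypes are reduced to zygosity states per bi-allelic variant: ``hom_ref``,
``het``, ``hom_alt`` or ``missing``.  Multi-allelic records are split into one
bi-allelic variant per alternate allele, so a diploid ``1/2`` call becomes a
``het`` for each of the two alleles.  Phasing is ignored (the downstream
segregation rules depend only on zygosity); half-calls such as ``./1`` are
conservatively treated as missing; haploid calls keep their presence
semantics (``1`` -> hom_alt, ``0`` -> hom_ref).

Annotations (gene symbol, categorical predictor labels, population allele
frequency) are supplied as a TSV keyed by (chrom, pos, ref, alt) — never by
rsid, which is not unique per allele — and joined to the genotype matrix
before filtering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .consensus import TOOL_COLUMNS

logger = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

CODE_TO_STATE = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}
STATE_TO_CODE = {v: k for k, v in CODE_TO_STATE.items()}

_ANN_FIXED_COLUMNS = ("chrom", "pos", "ref", "alt", "rsid", "gene", "maf")


class VariantFileError(ValueError):
    """Malformed variant or annotation input."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A bi-allelic variant: chromosome, 1-based position, ref and one alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantFileError(f"position {self.pos} is not 1-based")
        if "," in self.alt:
            raise VariantFileError(f"{self}: alt must be a single allele")

    def __str__(self) -> str:  # used in log and error messages
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def _chrom_sort_key(chrom: str) -> tuple:
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def genomic_order(key: VariantKey) -> tuple:
    return (*_chrom_sort_key(key.chrom), key.pos, key.ref, key.alt)


@dataclass
class GenotypeMatrix:
    """Zygosity calls for every (variant, sample) pair.

    ``codes`` is an int8 array of shape (n_variants, n_samples) holding
    HOM_REF/HET/HOM_ALT/MISSING.
    """

    variants: list[VariantKey]
    samples: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.variants), len(self.samples)):
            raise VariantFileError(
                f"genotype matrix shape {self.codes.shape} inconsistent with "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_column(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise VariantFileError(f"sample {sample!r} not present in genotype matrix") from None

    def states(self, variant_index: int, sample_ids: Sequence[str]) -> list[str]:
        """Zygosity state names for one variant across the given samples."""
        row = self.codes[variant_index]
        return [CODE_TO_STATE[int(row[self.sample_column(s)])] for s in sample_ids]


def _code_from_alleles(alleles: tuple, alt_index: int) -> int:
    """Map a pysam GT tuple to a zygosity code for one alternate allele."""
    if len(alleles) == 0 or all(a is None for a in alleles):
        return MISSING
    if any(a is None for a in alleles):  # half-call
        return MISSING
    if len(alleles) == 1:  # haploid
        return HOM_ALT if alleles[0] == alt_index else HOM_REF
    n_alt = sum(1 for a in alleles if a == alt_index)
    return {0: HOM_REF, 1: HET, 2: HOM_ALT}[n_alt]


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into one bi-allelic variant per alt
    allele.  Input order is preserved; sorting is not required.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        if "GT" not in vcf.header.formats:
            raise VariantFileError(f"{path}: VCF has no GT FORMAT field")
        samples = list(vcf.header.samples)
        variants: list[VariantKey] = []
        rows: list[list[int]] = []
        for rec in vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                variants.append(VariantKey(rec.chrom, rec.pos, rec.ref, alt))
                row = []
                for s in samples:
                    gt = rec.samples[s].get("GT", (None,))
                    row.append(_code_from_alleles(tuple(gt), alt_index))
                rows.append(row)
    codes = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(variants=variants, samples=samples, codes=codes)


_GT_FROM_CODE = {
    HOM_REF: (0, 0),
    HET: (0, 1),
    HOM_ALT: (1, 1),
    MISSING: (None, None),
}


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a bi-allelic :class:`GenotypeMatrix` as an uncompressed VCF."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(v.chrom for v in gm.variants):
        header.add_line(f"##contig=<ID={chrom}>")
    for s in gm.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, key in enumerate(gm.variants):
            rec = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            for j, s in enumerate(gm.samples):
                rec.samples[s]["GT"] = _GT_FROM_CODE[int(gm.codes[i, j])]
            out.write(rec)


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant annotation: gene symbol, predictor labels, population MAF."""

    key: VariantKey
    gene_symbol: str
    rsid: str | None = None
    predictor_labels: dict[str, str] = field(default_factory=dict)
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise VariantFileError(f"{self.key}: maf {self.maf} outside [0, 1]")
        unknown = set(self.predictor_labels) - set(TOOL_COLUMNS)
        if unknown:
            raise VariantFileError(
                f"{self.key}: unknown predictor tools {sorted(unknown)}; "
                f"accepted: {list(TOOL_COLUMNS)}"
            )


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read the per-variant annotation TSV.

    Columns: ``chrom, pos, ref, alt`` (the join key), optional ``rsid`` and
    ``maf``, ``gene``, and one column per predictor tool.  Blank predictor
    cells mean the tool made no call.  Unrecognised extra columns are
    rejected, naming the accepted tool columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("chrom", "pos", "ref", "alt", "gene")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VariantFileError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in _ANN_FIXED_COLUMNS]
    bad = [c for c in extra if c not in TOOL_COLUMNS]
    if bad:
        raise VariantFileError(
            f"{path}: unrecognised columns {bad}; accepted tool columns: "
            f"{list(TOOL_COLUMNS)}"
        )
    tool_cols = [c for c in extra]

    records: list[AnnotationRecord] = []
    for _, row in df.iterrows():
        key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        maf_cell = row.get("maf", "").strip() if "maf" in df.columns else ""
        maf = float(maf_cell) if maf_cell else None
        rsid_cell = row.get("rsid", "").strip() if "rsid" in df.columns else ""
        labels = {t: row[t].strip() for t in tool_cols if row[t].strip()}
        records.append(
            AnnotationRecord(
                key=key,
                gene_symbol=row["gene"].strip(),
                rsid=rsid_cell or None,
                predictor_labels=labels,
                maf=maf,
            )
        )
    return records


def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write annotation records as TSV (inverse of :func:`read_annotations`)."""
    rows = []
    for r in records:
        row = {
            "chrom": r.key.chrom,
            "pos": r.key.pos,
            "ref": r.key.ref,
            "alt": r.key.alt,
            "rsid": r.rsid or "",
            "gene": r.gene_symbol,
            "maf": "" if r.maf is None else repr(r.maf),
        }
        for t in TOOL_COLUMNS:
            row[t] = r.predictor_labels.get(t, "")
        rows.append(row)
    cols = list(_ANN_FIXED_COLUMNS) + list(TOOL_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class JoinedVariant:
    """A genotyped variant paired with its annotation row."""

    index: int  # row index into the GenotypeMatrix
    key: VariantKey
    annotation: AnnotationRecord


def join_variants(
    gm: GenotypeMatrix, annotations: Sequence[AnnotationRecord]
) -> list[JoinedVariant]:
    """Inner-join genotypes with annotations on (chrom, pos, ref, alt).

    Variants without an annotation are logged and excluded from gene-level
    steps.  Duplicate annotation rows for one key are an error.
    """
    by_key: dict[VariantKey, AnnotationRecord] = {}
    for ann in annotations:
        if ann.key in by_key:
            raise VariantFileError(f"duplicate annotation rows for {ann.key}")
        by_key[ann.key] = ann
    joined: list[JoinedVariant] = []
    unannotated = 0
    for i, key in enumerate(gm.variants):
        ann = by_key.get(key)
        if ann is None:
            unannotated += 1
            logger.debug("no annotation for %s; excluded from gene-level steps", key)
            continue
        joined.append(JoinedVariant(index=i, key=key, annotation=ann))
    if unannotated:
        logger.info("%d of %d variants lack annotation and were excluded",
                    unannotated, gm.n_variants)
    return joined
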