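"""Haplotype panel input/output and synthetic panel simulation.

A haplotype panel is an ``h x w`` binary matrix: one row per phased
haplotype, one column per bi-allelic variant site.  Panels are read from
phased VCF/BCF (one row per haplotype, i.e. two rows per diploid sample)
or from a plain text 0/1 matrix.  The synthetic generator produces the
repetitive, mosaic-of-founders panels typical of large cohort data, which
is the regime a run-length compressed PBWT index is designed for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PanelFormatError",
    "SiteMeta",
    "HaplotypePanel",
    "QueryPattern",
    "SMEMReportRecord",
    "read_vcf",
    "read_plain",
    "write_plain",
    "read_queries_plain",
    "synth_panel",
    "synth_query",
    "write_smems_tsv",
    "read_smems_tsv",
]


class PanelFormatError(ValueError):
    """Raised when an input file violates the panel format contract."""


@dataclass(frozen=True)
class SiteMeta:
    """Genomic metadata for one variant site (column)."""

    chrom: str
    pos: int  # 1-based genomic position
    ref: str
    alt: str


@dataclass
class HaplotypePanel:
    """An ``h x w`` matrix of 0/1 alleles with row labels.

    Parameters
    ----------
    alleles
        ``(h, w)`` uint8 array with values in {0, 1}.
    haplotype_ids
        One unique label per row.
    site_meta
        Optional per-column genomic metadata (chromosome, position,
        ref/alt allele), present when the panel came from a VCF.
    """

    alleles: np.ndarray
    haplotype_ids: list[str]
    site_meta: Optional[list[SiteMeta]] = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise PanelFormatError("alleles must be a 2-D matrix")
        h, w = self.alleles.shape
        if h < 1 or w < 1:
            raise PanelFormatError("panel must have at least one row and one column")
        if not np.isin(self.alleles, (0, 1)).all():
            raise PanelFormatError("alleles must be 0 or 1")
        if len(self.haplotype_ids) != h:
            raise PanelFormatError("haplotype_ids length must equal row count")
        if len(set(self.haplotype_ids)) != h:
            raise PanelFormatError("haplotype_ids must be unique")
        if self.site_meta is not None and len(self.site_meta) != w:
            raise PanelFormatError("site_meta length must equal column count")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def sequence(self, k: int) -> np.ndarray:
        """Row ``k`` (1-based) as a length-``w`` array."""
        return self.alleles[k - 1]


@dataclass
class QueryPattern:
    """A single query haplotype of the same width as the panel."""

    pattern_id: str
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8).ravel()
        if not np.isin(self.alleles, (0, 1)).all():
            raise PanelFormatError("query alleles must be 0 or 1")

    def __len__(self) -> int:
        return self.alleles.shape[0]


@dataclass
class SMEMReportRecord:
    """One set-maximal exact match of a query against the panel.

    Columns are 1-based inclusive site indices of the panel
    (``end_column = start_column + length - 1``).  ``occurrence_row_ids``
    is empty when only finding was requested and lists the sharing panel
    haplotypes when locating was requested.
    """

    query_id: str
    start_column: int
    length: int
    occurrence_row_ids: list[str] = field(default_factory=list)

    @property
    def end_column(self) -> int:
        return self.start_column + self.length - 1

    def __post_init__(self) -> None:
        if self.length < 1 or self.start_column < 1:
            raise ValueError("SMEM must have start_column >= 1 and length >= 1")


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, expand_diploid: bool = True) -> HaplotypePanel:
    """Read a phased VCF/BCF into a binary haplotype panel.

    Each sample contributes one row per haplotype: a diploid genotype
    ``a|b`` contributes rows ``<sample>_1`` (left allele) then
    ``<sample>_2``.  Records that are not bi-allelic are skipped and the
    skip count is logged.  Missing genotypes and unphased heterozygous
    separators are hard errors: the index is defined only over {0, 1}.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise PanelFormatError(f"{path}: VCF has no samples")
        columns: list[list[int]] = []
        meta: list[SiteMeta] = []
        n_skipped = 0
        ploidies: Optional[list[int]] = None
        for rec in vf:
            alts = rec.alts
            if alts is None or len(alts) != 1 or rec.ref is None:
                n_skipped += 1
                continue
            col: list[int] = []
            rec_ploidies: list[int] = []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    raise PanelFormatError(
                        f"{path}: missing genotype for sample {s} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                if len(gt) > 1 and not call.phased:
                    raise PanelFormatError(
                        f"{path}: unphased genotype for sample {s} at "
                        f"{rec.chrom}:{rec.pos} (phased '|' separator required)"
                    )
                if len(gt) > 1 and not expand_diploid:
                    raise PanelFormatError(
                        f"{path}: diploid genotype for sample {s} with "
                        "expand_diploid disabled"
                    )
                col.extend(int(a) for a in gt)
                rec_ploidies.append(len(gt))
            if ploidies is None:
                ploidies = rec_ploidies
            elif ploidies != rec_ploidies:
                raise PanelFormatError(f"{path}: inconsistent ploidy across records")
            columns.append(col)
            meta.append(SiteMeta(str(rec.chrom), int(rec.pos), rec.ref, alts[0]))
    if n_skipped:
        logger.info("read_vcf: skipped %d non-bi-allelic record(s)", n_skipped)
    if not columns:
        raise PanelFormatError(f"{path}: zero usable sites")
    assert ploidies is not None
    ids: list[str] = []
    for s, p in zip(samples, ploidies):
        if p == 1:
            ids.append(s)
        else:
            ids.extend(f"{s}_{k}" for k in range(1, p + 1))
    alleles = np.array(columns, dtype=np.uint8).T
    return HaplotypePanel(alleles, ids, meta)


# ---------------------------------------------------------------------------
# Plain text 0/1 matrix
# ---------------------------------------------------------------------------

def read_plain(path: str | Path) -> HaplotypePanel:
    """Read a plain text panel: one haplotype per line, characters in {0,1}."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise PanelFormatError(f"{path}: empty panel file")
    w = len(lines[0])
    rows = []
    for k, ln in enumerate(lines, start=1):
        if len(ln) != w:
            raise PanelFormatError(
                f"{path}: line {k} has length {len(ln)}, expected {w}"
            )
        if set(ln) - {"0", "1"}:
            raise PanelFormatError(f"{path}: line {k} has characters outside 0/1")
        rows.append([int(c) for c in ln])
    ids = [f"H{k}" for k in range(1, len(rows) + 1)]
    return HaplotypePanel(np.array(rows, dtype=np.uint8), ids)


def write_plain(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the allele matrix as one 0/1 line per haplotype."""
    with open(path, "w") as fh:
        for row in panel.alleles:
            fh.write("".join(map(str, row.tolist())) + "\n")


def read_queries_plain(path: str | Path) -> list[QueryPattern]:
    """Read query haplotypes from a plain 0/1 matrix, one query per line."""
    qp = read_plain(path)
    return [
        QueryPattern(f"Q{k + 1}", qp.alleles[k]) for k in range(qp.n_haplotypes)
    ]


# ---------------------------------------------------------------------------
# Synthetic panels and queries
# ---------------------------------------------------------------------------

def synth_panel(
    h: int,
    w: int,
    n_founders: int = 4,
    switch_rate: float = 0.02,
    mut_rate: float = 0.01,
    seed: int = 0,
) -> HaplotypePanel:
    """Simulate a repetitive biobank-like panel of founder mosaics.

    ``n_founders`` i.i.d. Bernoulli(0.5) founder haplotypes are drawn;
    each of the ``h`` output rows copies one founder, switching to a
    uniformly chosen founder with probability ``switch_rate`` at each
    site (a crude recombination model), then each allele is flipped with
    probability ``mut_rate``.  Few founders and low rates give a highly
    run-compressible PBWT, mimicking real cohort panels.
    """
    if h < 1 or w < 1:
        raise ValueError("h and w must be positive")
    if not 1 <= n_founders <= h:
        raise ValueError("need 1 <= n_founders <= h")
    for name, rate in (("switch_rate", switch_rate), ("mut_rate", mut_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    founders = rng.integers(0, 2, size=(n_founders, w), dtype=np.uint8)
    idx = np.empty((h, w), dtype=np.int64)
    idx[:, 0] = rng.integers(0, n_founders, size=h)
    for j in range(1, w):
        switch = rng.random(h) < switch_rate
        fresh = rng.integers(0, n_founders, size=h)
        idx[:, j] = np.where(switch, fresh, idx[:, j - 1])
    alleles = founders[idx, np.arange(w)]
    flips = rng.random((h, w)) < mut_rate
    alleles = (alleles ^ flips).astype(np.uint8)
    ids = [f"H{k}" for k in range(1, h + 1)]
    return HaplotypePanel(alleles, ids)


def synth_query(
    panel: HaplotypePanel,
    n_segments: int = 3,
    mut_rate: float = 0.01,
    seed: int = 0,
    pattern_id: str = "Q1",
) -> QueryPattern:
    """Build a mosaic query: contiguous blocks copied from random panel rows.

    The site range is split into ``n_segments`` near-equal contiguous
    blocks, each copied from a uniformly chosen panel row, then alleles
    are flipped with probability ``mut_rate``.  This guarantees long
    shared substrings so SMEM queries are non-trivial.
    """
    w = panel.n_sites
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > w:
        raise ValueError(f"n_segments={n_segments} exceeds panel width {w}")
    if not 0.0 <= mut_rate <= 1.0:
        raise ValueError("mut_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.empty(w, dtype=np.uint8)
    for block in np.array_split(np.arange(w), n_segments):
        src = rng.integers(0, panel.n_haplotypes)
        out[block] = panel.alleles[src, block]
    flips = rng.random(w) < mut_rate
    out = (out ^ flips).astype(np.uint8)
    return QueryPattern(pattern_id, out)


# ---------------------------------------------------------------------------
# SMEM report
# ---------------------------------------------------------------------------

_TSV_HEADER = "query_id\tstart_column\tend_column\tlength\toccurrences"


def write_smems_tsv(
    records: Sequence[SMEMReportRecord],
    path: str | Path,
    site_meta: Optional[list[SiteMeta]] = None,
) -> None:
    """Write SMEMs as TSV, sorted by (query_id, start_column).

    Occurrence ids are comma-joined, or "." when only finding was run.
    When site metadata is available the genomic start/end positions are
    echoed as two extra columns.
    """
    header = _TSV_HEADER + ("\tstart_pos\tend_pos" if site_meta is not None else "")
    ordered = sorted(records, key=lambda r: (r.query_id, r.start_column, r.length))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for rec in ordered:
            occ = ",".join(rec.occurrence_row_ids) if rec.occurrence_row_ids else "."
            fields = [
                rec.query_id,
                str(rec.start_column),
                str(rec.end_column),
                str(rec.length),
                occ,
            ]
            if site_meta is not None:
                fields.append(str(site_meta[rec.start_column - 1].pos))
                fields.append(str(site_meta[rec.end_column - 1].pos))
            fh.write("\t".join(fields) + "\n")


def read_smems_tsv(path: str | Path) -> list[SMEMReportRecord]:
    """Parse a TSV written by :func:`write_smems_tsv`."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("query_id\t"):
        raise PanelFormatError(f"{path}: missing SMEM report header")
    out = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        qid, start, end, length, occ = parts[:5]
        rec = SMEMReportRecord(
            query_id=qid,
            start_column=int(start),
            length=int(length),
            occurrence_row_ids=[] if occ == "." else occ.split(","),
        )
        if rec.end_column != int(end):
            raise PanelFormatError(f"{path}: inconsistent end_column in line {ln!r}")
        out.append(rec)
    return out
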