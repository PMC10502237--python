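"""Shared fixtures: synthetic instances and a tiny hand-checkable VCF."""

from __future__ import annotations

import numpy as np
import pytest

from mupbwt import panel_io, rlpbwt_index


def random_instance(seed: int, h_range=(5, 50), w_range=(5, 60)):
    """One reproducible (panel, mosaic query) pair for oracle comparisons."""
    rng = np.random.default_rng(seed)
    h = int(rng.integers(h_range[0], h_range[1] + 1))
    w = int(rng.integers(w_range[0], w_range[1] + 1))
    n_founders = int(rng.integers(1, min(h, 6) + 1))
    panel = panel_io.synth_panel(
        h=h, w=w, n_founders=n_founders,
        switch_rate=0.02, mut_rate=0.01, seed=seed,
    )
    n_segments = int(rng.integers(1, min(w, 5) + 1))
    pattern = panel_io.synth_query(
        panel, n_segments=n_segments, mut_rate=0.02, seed=seed + 1
    )
    return panel, pattern


@pytest.fixture
def small_panel() -> panel_io.HaplotypePanel:
    """3x2 panel with distinct co-lexicographic prefix order."""
    return panel_io.HaplotypePanel(
        np.array([[0, 1], [1, 0], [0, 0]], dtype=np.uint8), ["r1", "r2", "r3"]
    )


@pytest.fixture
def mosaic_panel() -> panel_io.HaplotypePanel:
    return panel_io.synth_panel(h=20, w=30, n_founders=3, seed=11)


@pytest.fixture
def mosaic_index(mosaic_panel):
    return rlpbwt_index.build_index(mosaic_panel)


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
"""


def write_vcf(path, records: list[str]) -> str:
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
    return str(path)


@pytest.fixture
def diploid_vcf(tmp_path):
    """Two diploid samples, three bi-allelic SNVs, all GTs 0|1."""
    recs = [
        f"chr1\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t0|1"
        for pos in (100, 200, 300)
    ]
    return write_vcf(tmp_path / "panel.vcf", recs)
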