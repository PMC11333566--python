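"""Synthetic reference panels and diploid targets with controlled structure.

The generator emulates the structure the phasing preliminaries assume:
reference haplotypes are drawn independently per site from a per-site
alternative-allele frequency, and each target haplotype is a
template-switching mosaic of panel haplotypes — it copies one panel
haplotype and switches to another with a small per-site probability, the
minimal generative model under which K-best selection has signal and
set-maximal matches are long.  Two mosaic haplotypes are combined into an
unphased diploid genotype and per-site missingness is applied.  No
demographic simulation, recombination map or population structure is
modelled.

All randomness derives from the single ``seed`` field; every generator is
a pure function of (spec, arguments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from phaseprep.panel_io import HaplotypePanel, SiteMeta, TargetGenotypes


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic panel/target generator."""

    n_haps: int = 200
    n_sites: int = 500
    freq_lo: float = 0.05  # per-site ALT frequency drawn uniformly in [lo, hi]
    freq_hi: float = 0.95
    mosaic_copy_rate: float = 0.01  # per-site template-switch probability
    missing_rate: float = 0.02  # per-site target missingness
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("freq_lo", "freq_hi", "mosaic_copy_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.freq_lo > self.freq_hi:
            raise ValueError("freq_lo must not exceed freq_hi")
        if self.n_haps < 1 or self.n_sites < 0:
            raise ValueError("panel dimensions must be positive")


def _site_grid(n_sites: int) -> list[SiteMeta]:
    return [SiteMeta(chrom="1", pos=100 * (m + 1), ref_allele="A", alt_allele="G") for m in range(n_sites)]


def gen_panel(spec: SynthSpec) -> HaplotypePanel:
    """Draw a panel: per-site ALT frequency uniform in [lo, hi], alleles i.i.d."""
    rng = np.random.default_rng([spec.seed, 0])
    freqs = rng.uniform(spec.freq_lo, spec.freq_hi, size=spec.n_sites)
    rows = (rng.random((spec.n_sites, spec.n_haps)) < freqs[:, None]).astype(np.uint8)
    names = [f"S{i}" for i in range(spec.n_haps // 2)]
    return HaplotypePanel(rows=rows, sites=_site_grid(spec.n_sites), sample_names=names)


def _mosaic_haplotype(panel: HaplotypePanel, rng: np.random.Generator, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One template-switching copy of the panel; returns (haplotype, template path)."""
    m = panel.n_sites
    templates = np.empty(m, dtype=np.int64)
    hap = np.empty(m, dtype=np.uint8)
    current = int(rng.integers(panel.n_haps))
    for site in range(m):
        if site > 0 and rng.random() < rate:
            current = int(rng.integers(panel.n_haps))
        templates[site] = current
        hap[site] = panel.rows[site, current]
    return hap, templates


def gen_targets(
    panel: HaplotypePanel, spec: SynthSpec, n_samples: int
) -> tuple[list[TargetGenotypes], np.ndarray]:
    """Sample diploid targets as pairs of mosaic haplotypes.

    Returns the unphased targets on the panel grid and the truth
    haplotypes, shape (n_samples, 2, M), for downstream evaluation.
    """
    if panel.n_sites == 0 or panel.n_haps == 0:
        raise ValueError("panel must be nonempty")
    rng = np.random.default_rng([spec.seed, 1])
    m = panel.n_sites
    truth = np.empty((n_samples, 2, m), dtype=np.uint8)
    targets: list[TargetGenotypes] = []
    for s in range(n_samples):
        h1, _ = _mosaic_haplotype(panel, rng, spec.mosaic_copy_rate)
        h2, _ = _mosaic_haplotype(panel, rng, spec.mosaic_copy_rate)
        truth[s, 0] = h1
        truth[s, 1] = h2
        missing = (rng.random(m) < spec.missing_rate).astype(np.uint8)
        dosage = h1.astype(np.int64) + h2.astype(np.int64)
        present = missing == 0
        is0 = ((dosage == 0) & present).astype(np.uint8)
        is2 = ((dosage == 2) & present).astype(np.uint8)
        het = ((dosage == 1) & present).astype(np.uint8)
        targets.append(
            TargetGenotypes(is0=is0, is2=is2, missing=missing, call=het, name=f"T{s}")
        )
    return targets, truth
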