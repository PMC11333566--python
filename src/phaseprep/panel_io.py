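"""Reference-panel and target-genotype I/O and the package-wide bit conventions.

Haplotype data is held variant-major: one bit row per site, one bit per
haplotype (0 = reference allele, 1 = alternative allele).  Diploid target
genotypes are encoded as per-site bitstreams: ``is0`` marks homozygous
reference sites, ``is2`` homozygous alternative sites, ``missing`` untyped
sites, and ``call`` the sites whose phase must be decided — under this
package's convention exactly the heterozygous sites.  Missing genotypes are
consistent with every haplotype and are left to the downstream imputation
step; they are never call sites.

Bit order is LSB-first everywhere: bit ``i`` of a stream maps to bit
``i mod w`` of word ``i // w``.  The same single convention covers 16-bit
bus words, 32-bit output words and 512-bit DRAM words.

Binary fixture format for a bit matrix (little-endian throughout)::

    bytes 0-3   magic  b"PPBM"
    byte  4     format version (1)
    bytes 5-8   uint32 N   (bits per row)
    bytes 9-12  uint32 M   (number of rows)
    then M rows, each ceil(N/8) bytes, bits packed LSB-first,
    padding bits in the last byte of a row are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MATRIX_MAGIC = b"PPBM"
MATRIX_VERSION = 1

_ALLOWED_WORD_WIDTHS = (16, 32, 512)


@dataclass(frozen=True)
class SiteMeta:
    """VCF-level identity of one biallelic site."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str


@dataclass
class HaplotypePanel:
    """Bit-packed variant-major matrix of N phased reference haplotypes over M sites.

    ``rows[m, n]`` is the allele of haplotype ``n`` at site ``m``.  Haplotypes
    ``2s`` and ``2s+1`` are the two chromosomes of reference sample ``s``.
    The panel admits no missing alleles.
    """

    rows: np.ndarray  # (M, N) uint8, values 0/1
    sites: list[SiteMeta] = field(default_factory=list)
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = np.ascontiguousarray(self.rows, dtype=np.uint8)
        if self.rows.ndim != 2:
            raise ValueError("panel rows must be a 2-D bit matrix")
        if self.sites and len(self.sites) != self.rows.shape[0]:
            raise ValueError("site metadata length does not match row count")

    @property
    def n_sites(self) -> int:
        return self.rows.shape[0]

    @property
    def n_haps(self) -> int:
        return self.rows.shape[1]


@dataclass
class TargetGenotypes:
    """Per-site genotype bitstreams of one diploid target on the panel site grid."""

    is0: np.ndarray
    is2: np.ndarray
    missing: np.ndarray
    call: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("is0", "is2", "missing", "call"):
            setattr(self, attr, np.ascontiguousarray(getattr(self, attr), dtype=np.uint8))
        m = self.is0.shape[0]
        if not (self.is2.shape[0] == self.missing.shape[0] == self.call.shape[0] == m):
            raise ValueError("genotype bitstreams must share one length")
        if np.any(self.is0 & self.is2):
            raise ValueError("a site cannot be both homozygous reference and homozygous alternative")
        if np.any(self.missing & (self.is0 | self.is2)):
            raise ValueError("a missing site cannot carry a homozygous genotype")
        het = 1 - (self.is0 | self.is2 | self.missing)
        if np.any(self.call & ~het):
            raise ValueError("call sites must be heterozygous sites")

    @property
    def n_sites(self) -> int:
        return self.is0.shape[0]

    @property
    def het(self) -> np.ndarray:
        """Heterozygous-site indicator; identical to ``call`` by construction."""
        return (1 - (self.is0 | self.is2 | self.missing)).astype(np.uint8)


# ---------------------------------------------------------------------------
# bit packing


def pack_bits(bits: Sequence[int] | np.ndarray, word_width: int) -> list[int]:
    """Pack a 0/1 stream into words, LSB-first.

    Bit ``i`` of the stream becomes bit ``i mod word_width`` of word
    ``i // word_width``; a final partial word is zero-padded.  Words are
    returned as Python integers so the 512-bit DRAM width needs no special
    casing.
    """
    if word_width not in _ALLOWED_WORD_WIDTHS:
        raise ValueError(f"word_width must be one of {_ALLOWED_WORD_WIDTHS}")
    arr = np.asarray(bits, dtype=np.uint8)
    words: list[int] = []
    for start in range(0, len(arr), word_width):
        chunk = arr[start : start + word_width]
        word = 0
        for j, b in enumerate(chunk):
            if b:
                word |= 1 << j
        words.append(word)
    return words


def unpack_bits(words: Iterable[int], n_bits: int, word_width: int) -> np.ndarray:
    """Inverse of :func:`pack_bits`; returns ``n_bits`` bits as uint8."""
    if word_width not in _ALLOWED_WORD_WIDTHS:
        raise ValueError(f"word_width must be one of {_ALLOWED_WORD_WIDTHS}")
    out = np.zeros(n_bits, dtype=np.uint8)
    i = 0
    for word in words:
        for j in range(word_width):
            if i >= n_bits:
                return out
            out[i] = (word >> j) & 1
            i += 1
    if i < n_bits:
        raise ValueError("not enough words for the requested bit count")
    return out


def _pack_row_bytes(row: np.ndarray) -> bytes:
    return np.packbits(row.astype(np.uint8), bitorder="little").tobytes()


def _unpack_row_bytes(buf: bytes, n_bits: int) -> np.ndarray:
    return np.unpackbits(np.frombuffer(buf, dtype=np.uint8), bitorder="little")[:n_bits]


# ---------------------------------------------------------------------------
# binary bit-matrix fixtures


def write_matrix(path: str | Path, rows: np.ndarray) -> None:
    """Write a bit matrix in the documented fixture format."""
    rows = np.ascontiguousarray(rows, dtype=np.uint8)
    m, n = rows.shape
    with open(path, "wb") as fh:
        fh.write(MATRIX_MAGIC)
        fh.write(bytes([MATRIX_VERSION]))
        fh.write(np.uint32(n).tobytes())
        fh.write(np.uint32(m).tobytes())
        for row in rows:
            fh.write(_pack_row_bytes(row))


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a bit matrix written by :func:`write_matrix`."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != MATRIX_MAGIC:
            raise ValueError(f"{path}: not a phaseprep bit-matrix file")
        version = fh.read(1)[0]
        if version != MATRIX_VERSION:
            raise ValueError(f"{path}: unsupported bit-matrix version {version}")
        n = int(np.frombuffer(fh.read(4), dtype=np.uint32)[0])
        m = int(np.frombuffer(fh.read(4), dtype=np.uint32)[0])
        row_bytes = (n + 7) // 8
        rows = np.empty((m, n), dtype=np.uint8)
        for i in range(m):
            buf = fh.read(row_bytes)
            if len(buf) != row_bytes:
                raise ValueError(f"{path}: truncated bit-matrix file")
            rows[i] = _unpack_row_bytes(buf, n)
    return rows


# ---------------------------------------------------------------------------
# VCF


def read_reference_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased biallelic reference VCF into a variant-major bit matrix.

    Every GT field must be diploid and phased ("|"); any missing allele,
    unphased separator, haploid call or multi-allelic record is an error.
    Haplotype ``2s + h`` is allele ``h`` of sample ``s``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = 2 * len(samples)
    rows: list[np.ndarray] = []
    sites: list[SiteMeta] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} is not biallelic (ALT={rec.ALT})"
            )
        row = np.empty(n, dtype=np.uint8)
        for s, gt in enumerate(rec.genotypes):
            # cyvcf2 genotype: [allele0, allele1, ..., phased_flag]
            alleles, phased = gt[:-1], gt[-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"{path}: sample {samples[s]} at {rec.CHROM}:{rec.POS} is not diploid"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                raise ValueError(
                    f"{path}: missing allele for sample {samples[s]} at {rec.CHROM}:{rec.POS}"
                )
            if not phased:
                raise ValueError(
                    f"{path}: unphased genotype for sample {samples[s]} at {rec.CHROM}:{rec.POS}"
                )
            row[2 * s] = alleles[0]
            row[2 * s + 1] = alleles[1]
        rows.append(row)
        sites.append(SiteMeta(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    matrix = np.vstack(rows) if rows else np.zeros((0, n), dtype=np.uint8)
    return HaplotypePanel(rows=matrix, sites=sites, sample_names=samples)


def read_targets_vcf(path: str | Path, panel_sites: Sequence[SiteMeta]) -> list[TargetGenotypes]:
    """Read unphased diploid targets onto the panel's site grid.

    Sites of the panel absent from the target file are marked missing; a
    target site absent from the panel, or any allele mismatch at a matched
    position, is an error (no strand harmonisation is attempted).
    """
    from cyvcf2 import VCF

    site_index = {(s.chrom, s.pos): (i, s) for i, s in enumerate(panel_sites)}
    m = len(panel_sites)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    is0 = np.zeros((len(samples), m), dtype=np.uint8)
    is2 = np.zeros((len(samples), m), dtype=np.uint8)
    het = np.zeros((len(samples), m), dtype=np.uint8)
    seen = np.zeros(m, dtype=bool)
    for rec in vcf:
        key = (rec.CHROM, rec.POS)
        if key not in site_index:
            raise ValueError(f"{path}: target site {rec.CHROM}:{rec.POS} not present in the panel")
        idx, meta = site_index[key]
        if len(rec.ALT) != 1:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} is not biallelic")
        if rec.REF != meta.ref_allele or rec.ALT[0] != meta.alt_allele:
            raise ValueError(
                f"{path}: allele mismatch at {rec.CHROM}:{rec.POS}: "
                f"panel {meta.ref_allele}>{meta.alt_allele}, target {rec.REF}>{rec.ALT[0]}"
            )
        seen[idx] = True
        for s, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"{path}: sample {samples[s]} at {rec.CHROM}:{rec.POS} is not diploid"
                )
            a, b = alleles
            if a < 0 or b < 0:
                continue  # stays missing
            dosage = a + b
            if dosage == 0:
                is0[s, idx] = 1
            elif dosage == 2:
                is2[s, idx] = 1
            else:
                het[s, idx] = 1
    targets = []
    for s, name in enumerate(samples):
        missing = (~(is0[s].astype(bool) | is2[s].astype(bool) | het[s].astype(bool))).astype(
            np.uint8
        )
        missing |= (~seen).astype(np.uint8)
        targets.append(
            TargetGenotypes(is0=is0[s], is2=is2[s], missing=missing, call=het[s], name=name)
        )
    return targets


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _write_vcf_lines(path: str | Path, lines: Iterable[str]) -> None:
    path = Path(path)
    if path.suffix == ".gz":
        import pysam

        with pysam.BGZFile(str(path), "wb") as fh:
            for line in lines:
                fh.write(line.encode())
    else:
        with open(path, "wt") as fh:
            for line in lines:
                fh.write(line)


def write_reference_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel back out as a phased VCF (inverse of :func:`read_reference_vcf`)."""
    if panel.n_haps % 2:
        raise ValueError("panel must contain an even number of haplotypes (diploid samples)")
    n_samples = panel.n_haps // 2
    names = panel.sample_names or [f"S{i}" for i in range(n_samples)]
    contigs = sorted({s.chrom for s in panel.sites}, key=str)

    def lines():
        yield _VCF_HEADER
        for c in contigs:
            yield f"##contig=<ID={c}>\n"
        yield "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n"
        for m, site in enumerate(panel.sites):
            gts = "\t".join(
                f"{panel.rows[m, 2 * s]}|{panel.rows[m, 2 * s + 1]}" for s in range(n_samples)
            )
            yield (
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t{site.alt_allele}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )

    _write_vcf_lines(path, lines())


def write_targets_vcf(
    targets: Sequence[TargetGenotypes], sites: Sequence[SiteMeta], path: str | Path
) -> None:
    """Write unphased diploid targets as VCF on the given site grid."""
    names = [t.name or f"T{i}" for i, t in enumerate(targets)]
    contigs = sorted({s.chrom for s in sites}, key=str)

    def gt_str(t: TargetGenotypes, m: int) -> str:
        if t.missing[m]:
            return "./."
        if t.is0[m]:
            return "0/0"
        if t.is2[m]:
            return "1/1"
        return "0/1"

    def lines():
        yield _VCF_HEADER
        for c in contigs:
            yield f"##contig=<ID={c}>\n"
        yield "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n"
        for m, site in enumerate(sites):
            gts = "\t".join(gt_str(t, m) for t in targets)
            yield (
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t{site.alt_allele}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )

    _write_vcf_lines(path, lines())
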