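"""Phased reference haplotype panels and LD (correlation) computation.

The panel is the source of the correlation structure used for imputation:
under the null hypothesis, association Z-scores at nearby SNPs are jointly
normal with correlation equal to the genotype LD, which we estimate from the
phased haplotypes of a reference population.  LD is computed on the 0/1
haplotype allele indicators (under Hardy-Weinberg equilibrium the diploid
dosage correlation has the same expectation).

Two input dialects are supported: VCF with phased GT, and IMPUTE-style
.hap/.legend pairs.  Only biallelic SNVs are retained; monomorphic and
rare sites (alt frequency below ``maf_min``) are dropped because their
correlations are unstable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .sumstats import normalize_chrom

log = logging.getLogger(__name__)

DEFAULT_MAF_MIN = 0.005

_CACHE_MAGIC = "zimpute-corr-cache-v1"


class PanelError(ValueError):
    """Malformed reference-panel input."""


class CacheMismatchError(ValueError):
    """Correlation cache does not match the panel/parameters; recompute it."""


@dataclass
class ReferencePanel:
    """Phased haplotypes with variant metadata.

    Attributes
    ----------
    chrom, pos, ref, alt : ndarray
        Per-variant metadata, sorted by (chrom, pos).  ``alt`` is the allele
        coded 1 in ``H``.
    H : ndarray of shape (n_hap, n_variant)
        Haplotype-by-variant 0/1 allele matrix.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    H: np.ndarray
    _std: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.uint8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.H.ndim != 2 or self.H.shape[1] != len(self.pos):
            raise PanelError("haplotype matrix and variant metadata disagree")
        if self.n_hap < 2:
            raise PanelError("need at least 2 haplotypes")

    @property
    def n_hap(self) -> int:
        return self.H.shape[0]

    @property
    def n_variant(self) -> int:
        return self.H.shape[1]

    @property
    def variants(self) -> list[tuple[str, int, str, str]]:
        """Ordered (chrom, pos, ref, alt) tuples."""
        return list(zip(self.chrom, self.pos.tolist(), self.ref, self.alt))

    def alt_freq(self, idx: int) -> float:
        """Alternate-allele frequency of one variant (mean haplotype column)."""
        return float(self.H[:, idx].mean())

    def alt_freqs(self) -> np.ndarray:
        return self.H.mean(axis=0)

    def checksum(self) -> str:
        """Content hash of haplotypes + variant metadata (keys the LD cache)."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.H).tobytes())
        meta = "\n".join(f"{c}\t{p}\t{r}\t{a}" for c, p, r, a in self.variants)
        h.update(meta.encode())
        return h.hexdigest()

    def standardized(self) -> np.ndarray:
        """Column-standardised haplotype matrix (cached); columns have unit
        population (ddof=0) standard deviation, so ``Xs.T @ Xs / n_hap`` is
        the correlation matrix."""
        if self._std is None:
            X = self.H.astype(np.float64)
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            if np.any(sd == 0):
                raise PanelError("monomorphic variant in panel; filter first")
            self._std = (X - mu) / sd
        return self._std


@dataclass
class CorrBlock:
    """A rectangular block of the variant correlation matrix."""

    row_ids: np.ndarray
    col_ids: np.ndarray
    R: np.ndarray


def corr_block(panel: ReferencePanel, row_ids, col_ids) -> CorrBlock:
    """Pearson correlation of haplotype allele indicators, rows x cols.

    Deterministic for a fixed panel.  When ``row_ids == col_ids`` the block
    is symmetrised and its diagonal set exactly to 1.
    """
    row_ids = np.asarray(row_ids, dtype=np.intp)
    col_ids = np.asarray(col_ids, dtype=np.intp)
    Xs = panel.standardized()
    R = Xs[:, row_ids].T @ Xs[:, col_ids] / panel.n_hap
    np.clip(R, -1.0, 1.0, out=R)
    if row_ids.shape == col_ids.shape and np.array_equal(row_ids, col_ids):
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
    return CorrBlock(row_ids=row_ids, col_ids=col_ids, R=R)


def _finalize_panel(chrom, pos, ref, alt, columns, maf_min: float) -> ReferencePanel:
    H = np.column_stack(columns).astype(np.uint8)
    freqs = H.mean(axis=0)
    keep = (freqs >= maf_min) & (freqs <= 1.0 - maf_min) & (H.std(axis=0) > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropped %d monomorphic/rare site(s) (maf_min=%g)", n_drop, maf_min)
    if not keep.any():
        raise PanelError("no polymorphic variants remain after filtering")
    idx = np.flatnonzero(keep)
    panel = ReferencePanel(
        chrom=np.array(chrom, dtype=object)[idx],
        pos=np.array(pos, dtype=np.int64)[idx],
        ref=np.array(ref, dtype=object)[idx],
        alt=np.array(alt, dtype=object)[idx],
        H=H[:, idx],
    )
    order = np.lexsort((panel.pos, np.array([_ck(c) for c in panel.chrom], dtype=object)))
    if not np.array_equal(order, np.arange(panel.n_variant)):
        panel = ReferencePanel(
            chrom=panel.chrom[order], pos=panel.pos[order],
            ref=panel.ref[order], alt=panel.alt[order], H=panel.H[:, order],
        )
    return panel


def _ck(chrom: str):
    return f"{int(chrom):09d}" if chrom.isdigit() else chrom


def _parse_region(region) -> tuple[str, int, int] | None:
    if region is None:
        return None
    if isinstance(region, str):
        chrom, _, span = region.partition(":")
        if span:
            start, _, end = span.partition("-")
            return normalize_chrom(chrom), int(start), int(end)
        return normalize_chrom(chrom), 1, np.iinfo(np.int64).max
    chrom, start, end = region
    return normalize_chrom(chrom), int(start), int(end)


def load_vcf_panel(path, region=None, maf_min: float = DEFAULT_MAF_MIN) -> ReferencePanel:
    """Load a phased VCF into a :class:`ReferencePanel`.

    Multiallelic records and indels are skipped (with logged counts); sites
    with missing genotypes are dropped with a warning; an unphased genotype
    at a retained site is an error.  ``region`` may be ``"chrom:start-end"``
    or a ``(chrom, start, end)`` tuple (1-based, inclusive); it is applied
    while streaming, so unindexed plain-text VCFs work.
    """
    from cyvcf2 import VCF

    reg = _parse_region(region)
    chrom, pos, ref, alt, cols = [], [], [], [], []
    n_skip_multi = n_skip_indel = n_skip_missing = 0
    vcf = VCF(str(path))
    for v in vcf:
        if len(v.ALT) != 1:
            n_skip_multi += 1
            continue
        if not v.is_snp:
            n_skip_indel += 1
            continue
        c = normalize_chrom(v.CHROM)
        if reg is not None and not (c == reg[0] and reg[1] <= v.POS <= reg[2]):
            continue
        gts = v.genotypes  # [allele0, allele1, phased] per sample
        alleles = np.array([g[:2] for g in gts], dtype=np.int64)
        if (alleles < 0).any():
            log.warning("missing genotype at %s:%d; site dropped", c, v.POS)
            n_skip_missing += 1
            continue
        if not all(g[2] for g in gts):
            raise PanelError(f"unphased genotype at {c}:{v.POS}; panel must be phased")
        chrom.append(c)
        pos.append(v.POS)
        ref.append(v.REF.upper())
        alt.append(v.ALT[0].upper())
        cols.append(alleles.reshape(-1))
    vcf.close()
    if n_skip_multi or n_skip_indel:
        log.info(
            "skipped %d multiallelic and %d non-SNV record(s)", n_skip_multi, n_skip_indel
        )
    if not cols:
        raise PanelError(f"no usable biallelic SNVs in {path}")
    return _finalize_panel(chrom, pos, ref, alt, cols, maf_min)


def load_hap_legend(
    hap_path, legend_path, chrom: str = "1", maf_min: float = DEFAULT_MAF_MIN
) -> ReferencePanel:
    """Load an IMPUTE-style reference: ``.legend`` (id position a0 a1, with
    header) and ``.hap`` (one row per variant, space-separated 0/1 per
    haplotype).  ``a1`` is the alt allele.  The legend carries no chromosome,
    so one is supplied via ``chrom``."""
    legend = []
    with open(legend_path) as fh:
        header = fh.readline().split()
        need = {"id", "position", "a0", "a1"}
        if not need <= set(header):
            raise PanelError(f"legend header must contain {sorted(need)}")
        ix = {k: header.index(k) for k in need}
        for line in fh:
            f = line.split()
            if f:
                legend.append((int(f[ix["position"]]), f[ix["a0"]], f[ix["a1"]]))
    rows = []
    with open(hap_path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            if any(x not in ("0", "1") for x in f):
                raise PanelError("hap file entries must be 0/1")
            rows.append(np.array(f, dtype=np.uint8))
    if len(rows) != len(legend):
        raise PanelError(
            f"legend has {len(legend)} row(s) but hap has {len(rows)}"
        )
    if not rows:
        raise PanelError("empty hap/legend input")
    n_hap = len(rows[0])
    if any(len(r) != n_hap for r in rows):
        raise PanelError("ragged hap rows")
    chrom_l = [normalize_chrom(chrom)] * len(legend)
    pos = [p for p, _, _ in legend]
    ref = [a0.upper() for _, a0, _ in legend]
    alt = [a1.upper() for _, _, a1 in legend]
    return _finalize_panel(chrom_l, pos, ref, alt, rows, maf_min)


def save_hap_legend(panel: ReferencePanel, hap_path, legend_path) -> None:
    """Write a panel in the IMPUTE-style dialect read by :func:`load_hap_legend`."""
    with open(legend_path, "w") as fh:
        fh.write("id position a0 a1\n")
        for c, p, r, a in panel.variants:
            fh.write(f"{c}:{p} {p} {r} {a}\n")
    with open(hap_path, "w") as fh:
        for j in range(panel.n_variant):
            fh.write(" ".join(map(str, panel.H[:, j])) + "\n")


# ---------------------------------------------------------------------------
# Pre-computed local correlation tables
# ---------------------------------------------------------------------------

def save_corr_cache(panel: ReferencePanel, plan, path, pred_size: int, flank_size: int) -> None:
    """Pre-compute and store each window's local correlation blocks.

    The file is a one-line JSON text header (panel checksum, window
    parameters, block shapes/offsets) followed by the raw float64 blocks, so
    a later run can impute without touching the haplotypes.  Loading checks
    the checksum and parameters and refuses to serve a stale cache.
    """
    headers = []
    blobs = []
    offset = 0
    for w in plan:
        typed = w.typed
        Stt = corr_block(panel, typed, typed).R
        Sut = corr_block(panel, w.targets, typed).R
        for name, M in (("Stt", Stt), ("Sut", Sut)):
            b = np.ascontiguousarray(M, dtype=np.float64).tobytes()
            headers.append({"name": name, "shape": list(M.shape), "offset": offset,
                            "nbytes": len(b)})
            blobs.append(b)
            offset += len(b)
    header = {
        "magic": _CACHE_MAGIC,
        "checksum": panel.checksum(),
        "pred_size": int(pred_size),
        "flank_size": int(flank_size),
        "n_windows": len(plan),
        "blocks": headers,
    }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode())
        for b in blobs:
            fh.write(b)


def load_corr_cache(path, panel: ReferencePanel, pred_size: int, flank_size: int):
    """Load cached correlation blocks; returns ``[(Stt, Sut), ...]`` per window.

    Raises :class:`CacheMismatchError` if the cache was built for a different
    panel or different window parameters.
    """
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        if header.get("magic") != _CACHE_MAGIC:
            raise CacheMismatchError(f"{path} is not a correlation cache")
        if header["checksum"] != panel.checksum():
            raise CacheMismatchError(
                "cache was built for a different panel; recompute it"
            )
        if header["pred_size"] != pred_size or header["flank_size"] != flank_size:
            raise CacheMismatchError(
                f"cache built with pred_size={header['pred_size']}, "
                f"flank_size={header['flank_size']}; recompute for "
                f"pred_size={pred_size}, flank_size={flank_size}"
            )
        payload = fh.read()
    blocks = []
    for meta in header["blocks"]:
        arr = np.frombuffer(
            payload, dtype=np.float64, count=int(np.prod(meta["shape"])),
            offset=meta["offset"],
        ).reshape(meta["shape"]).copy()
        blocks.append(arr)
    return [(blocks[2 * i], blocks[2 * i + 1]) for i in range(header["n_windows"])]
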