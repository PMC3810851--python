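"""Conditional-mean imputation of Z-scores at untyped SNPs.

Under the null hypothesis, the vector of association Z-scores at typed and
untyped SNPs is multivariate normal with zero mean and covariance equal to
the LD correlation matrix.  The imputation rule is therefore the conditional
expectation

    E[Z_u | Z_t] = S_ut (S_tt + lam I)^-1 Z_t,

where S_tt is the typed-typed and S_ut the untyped-typed correlation block
estimated from a reference panel, and ``lam`` is a small ridge term guarding
against the ill-conditioning of finite-panel LD estimates.  The per-SNP
imputation quality

    r2pred_i = [S_ut (S_tt + lam I)^-1 S_tu]_ii

is the null-hypothesis variance of the imputed statistic: 1 for a perfectly
tagged SNP, 0 for a SNP carrying no information from the typed set.

The genome is processed in sliding windows: the typed SNPs are partitioned
into consecutive *prediction windows* of ``pred_size`` SNPs, each untyped SNP
is assigned to exactly one prediction window by position, and the predictors
for a window are its core typed SNPs plus ``flank_size`` adjacent typed SNPs
on each side (the *extended window*).

The user-facing entry point is the :class:`DirectImputation` model whose
:meth:`~DirectImputation.fit` returns an :class:`ImputationResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import __version__ as _pkg_version
from .harmonize import HarmonizedSet, harmonize
from .panel import ReferencePanel, corr_block, load_corr_cache
from .sumstats import SumStatRecord, read_sumstats, write_results, z_to_p

log = logging.getLogger(__name__)

DEFAULT_PRED_SIZE = 100
DEFAULT_FLANK_SIZE = 250
DEFAULT_LAM = 1e-3
DEFAULT_MIN_R2PRED = 0.3

#: |r| above which one of a typed pair is pruned when the solve fails.
COLLINEAR_R = 0.999


class ImputationError(ValueError):
    pass


class SingularMatrixError(ImputationError):
    """The typed-typed correlation block is numerically singular."""


@dataclass
class ImputationWindow:
    """One prediction window: core typed SNPs, flanking typed SNPs, targets.

    All index arrays refer to positions in the harmonized panel ordering.
    ``typed`` is the extended-window predictor set (flanks + core, sorted).
    """

    core: np.ndarray
    flank_left: np.ndarray
    flank_right: np.ndarray
    targets: np.ndarray
    Stt: np.ndarray | None = None
    Sut: np.ndarray | None = None

    @property
    def typed(self) -> np.ndarray:
        return np.concatenate([self.flank_left, self.core, self.flank_right])


@dataclass
class ImputedRecord:
    """One output SNP: identity, Z, quality and provenance."""

    chrom: str
    pos: int
    a1: str  # effect allele == panel alt
    a2: str
    z_imp: float | None
    r2pred: float
    n_typed_used: int
    status: str  # typed | imputed | skipped

    @property
    def z(self) -> float | None:
        return self.z_imp

    @property
    def p(self) -> float | None:
        return None if self.z_imp is None else z_to_p(self.z_imp)


def plan_windows(
    hset: HarmonizedSet,
    pred_size: int = DEFAULT_PRED_SIZE,
    flank_size: int = DEFAULT_FLANK_SIZE,
) -> list[ImputationWindow]:
    """Partition the harmonized variants into prediction/extended windows.

    Typed variants are split per chromosome into consecutive runs of
    ``pred_size`` (the last run may be shorter).  Each untyped variant joins
    the window whose core's first typed SNP position is the largest one not
    exceeding its own position (half-open rule; untyped variants before the
    first typed SNP join the first window, after the last core start the
    last).  Flanks are the ``flank_size`` typed SNPs adjacent on each side,
    truncated at chromosome ends.
    """
    if pred_size < 1:
        raise ImputationError("pred_size must be >= 1")
    if flank_size < 0:
        raise ImputationError("flank_size must be >= 0")
    panel = hset.panel
    windows: list[ImputationWindow] = []
    for chrom in pd.unique(panel.chrom):
        on_chrom = np.flatnonzero(panel.chrom == chrom)
        typed = on_chrom[hset.typed_mask[on_chrom]]
        untyped = on_chrom[~hset.typed_mask[on_chrom]]
        if typed.size == 0:
            raise ImputationError(
                f"nothing to condition on: no typed variants on chromosome {chrom}"
            )
        cores = [typed[i : i + pred_size] for i in range(0, typed.size, pred_size)]
        starts = np.array([panel.pos[c[0]] for c in cores])
        # half-open assignment by the core's first typed-SNP position
        wix = np.clip(
            np.searchsorted(starts, panel.pos[untyped], side="right") - 1, 0, None
        )
        for k, core in enumerate(cores):
            lo = np.searchsorted(typed, core[0])
            hi = np.searchsorted(typed, core[-1], side="right")
            windows.append(
                ImputationWindow(
                    core=core,
                    flank_left=typed[max(0, lo - flank_size) : lo],
                    flank_right=typed[hi : hi + flank_size],
                    targets=untyped[wix == k],
                )
            )
    return windows


def impute_window(
    Zt: np.ndarray, Stt: np.ndarray, Sut: np.ndarray, lam: float = DEFAULT_LAM
) -> tuple[np.ndarray, np.ndarray]:
    """Impute one window: ``Zu = Sut (Stt + lam I)^-1 Zt`` and its quality.

    The solve uses a Cholesky factorisation of the (symmetric positive
    definite) regularised block, never an explicit inverse.  With ``lam=0``
    a near-singular ``Stt`` (smallest eigenvalue < 1e-10) raises
    :class:`SingularMatrixError` advising ``lam > 0`` or pruning.

    Returns
    -------
    (Zu, r2pred) : pair of ndarray
        Imputed Z-scores and their null variances, one entry per target.
    """
    Zt = np.asarray(Zt, dtype=np.float64)
    Stt = np.asarray(Stt, dtype=np.float64)
    Sut = np.atleast_2d(np.asarray(Sut, dtype=np.float64))
    if lam < 0:
        raise ImputationError("lam must be >= 0")
    t = Zt.shape[0]
    if Stt.shape != (t, t):
        raise ImputationError(f"Stt must be {t}x{t}, got {Stt.shape}")
    if not np.allclose(Stt, Stt.T, atol=1e-8):
        raise ImputationError("Stt must be symmetric")
    if Sut.shape[1] != t:
        raise ImputationError(f"Sut must have {t} columns, got {Sut.shape[1]}")
    if Sut.shape[0] == 0:
        return np.empty(0), np.empty(0)
    A = Stt + lam * np.eye(t)
    if lam < 1e-12 and t > 0:
        w_min = float(linalg.eigvalsh(A, subset_by_index=(0, 0))[0])
        if w_min < 1e-10:
            raise SingularMatrixError(
                f"typed-typed correlation block is singular (min eigenvalue "
                f"{w_min:.2e}); set lam > 0 or prune collinear SNPs"
            )
    try:
        c = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError as exc:
        raise SingularMatrixError(
            "typed-typed correlation block is not positive definite; "
            "set lam > 0 or prune collinear SNPs"
        ) from exc
    X = linalg.cho_solve(c, Sut.T)  # (t, u): A^-1 Sut'
    Zu = X.T @ Zt
    r2pred = np.einsum("ut,tu->u", Sut, X)
    np.clip(r2pred, 0.0, None, out=r2pred)
    return Zu, r2pred


def _prune_collinear(Stt: np.ndarray) -> np.ndarray:
    """Indices to keep after greedily dropping the later member of each
    typed pair with |r| > COLLINEAR_R (keeps the lower-position SNP)."""
    t = Stt.shape[0]
    keep: list[int] = []
    for j in range(t):
        if all(abs(Stt[j, i]) <= COLLINEAR_R for i in keep):
            keep.append(j)
    return np.array(keep, dtype=np.intp)


def impute_all(
    hset: HarmonizedSet,
    panel: ReferencePanel | None = None,
    pred_size: int = DEFAULT_PRED_SIZE,
    flank_size: int = DEFAULT_FLANK_SIZE,
    lam: float = DEFAULT_LAM,
    min_r2pred: float = DEFAULT_MIN_R2PRED,
    rescale: bool = False,
    corr_cache=None,
    windows: list[ImputationWindow] | None = None,
) -> list[ImputedRecord]:
    """Impute every untyped panel variant; pass typed variants through.

    Correlation blocks come from the panel haplotypes, or from a
    pre-computed cache (``corr_cache``: a path, or the block list returned by
    :func:`zimpute.panel.load_corr_cache`) which gives bit-identical results.
    Targets with quality below ``min_r2pred`` are reported with status
    ``skipped``.  A window whose typed block fails the positive-definite
    check is retried after pruning one member of each collinear pair.  With
    ``rescale`` the reported Z is ``Zu / sqrt(r2pred)`` (unit null variance)
    instead of the raw conditional mean.
    """
    panel = panel if panel is not None else hset.panel
    if windows is None:
        windows = plan_windows(hset, pred_size, flank_size)
    if isinstance(corr_cache, (str, bytes)) or hasattr(corr_cache, "__fspath__"):
        corr_cache = load_corr_cache(corr_cache, panel, pred_size, flank_size)
    if corr_cache is not None and len(corr_cache) != len(windows):
        raise ImputationError(
            f"cache has {len(corr_cache)} window(s), plan has {len(windows)}"
        )

    out: dict[int, ImputedRecord] = {}
    for i in hset.typed_indices:
        out[i] = _record(panel, i, float(hset.z[i]), 1.0, 0, "typed")

    for k, w in enumerate(windows):
        typed = w.typed
        if w.targets.size == 0:
            continue
        if corr_cache is not None:
            Stt, Sut = corr_cache[k]
        else:
            Stt = corr_block(panel, typed, typed).R
            Sut = corr_block(panel, w.targets, typed).R
        w.Stt, w.Sut = Stt, Sut
        Zt = hset.z[typed]
        try:
            Zu, r2 = impute_window(Zt, Stt, Sut, lam)
        except SingularMatrixError:
            keep = _prune_collinear(Stt)
            log.warning(
                "window %d: typed block not PD; pruned %d collinear SNP(s)",
                k, typed.size - keep.size,
            )
            Zu, r2 = impute_window(Zt[keep], Stt[np.ix_(keep, keep)], Sut[:, keep], lam)
            typed = typed[keep]
        for j, tgt in enumerate(w.targets):
            q = float(min(r2[j], 1.0))
            if q < min_r2pred:
                out[tgt] = _record(panel, tgt, None, q, typed.size, "skipped")
            else:
                z = float(Zu[j])
                if rescale and q > 0:
                    z /= np.sqrt(q)
                out[tgt] = _record(panel, tgt, z, q, typed.size, "imputed")
    return [out[i] for i in sorted(out)]


def _record(panel, i, z, r2, n_typed, status) -> ImputedRecord:
    return ImputedRecord(
        chrom=panel.chrom[i], pos=int(panel.pos[i]),
        a1=panel.alt[i], a2=panel.ref[i],
        z_imp=z, r2pred=r2, n_typed_used=n_typed, status=status,
    )


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------

class DirectImputation:
    """Direct summary-statistic imputation model.

    Binds a set of summary statistics to a reference panel and holds the
    imputation parameters; :meth:`fit` harmonises, windows and imputes,
    returning an :class:`ImputationResults`.

    Parameters
    ----------
    sumstats : sequence of SumStatRecord
        Typed association statistics (effect allele = a1).
    panel : ReferencePanel
        Phased reference haplotypes supplying the LD structure.
    pred_size, flank_size : int
        Number of typed SNPs per prediction window and per extended-window
        flank.
    lam : float
        Ridge term added to the typed-typed correlation diagonal.
    min_r2pred : float
        Quality threshold below which imputed SNPs are reported as skipped.
    keep_ambiguous : bool
        Keep strand-ambiguous (A/T, C/G) SNPs instead of dropping them.
    rescale : bool
        Report ``Zu / sqrt(r2pred)`` instead of the raw conditional mean.
    """

    def __init__(
        self,
        sumstats,
        panel: ReferencePanel,
        pred_size: int = DEFAULT_PRED_SIZE,
        flank_size: int = DEFAULT_FLANK_SIZE,
        lam: float = DEFAULT_LAM,
        min_r2pred: float = DEFAULT_MIN_R2PRED,
        keep_ambiguous: bool = False,
        rescale: bool = False,
    ) -> None:
        if pred_size < 1:
            raise ImputationError("pred_size must be >= 1")
        if flank_size < 0:
            raise ImputationError("flank_size must be >= 0")
        if lam < 0:
            raise ImputationError("lam must be >= 0")
        if not (0.0 <= min_r2pred <= 1.0):
            raise ImputationError("min_r2pred must be in [0, 1]")
        self.sumstats = list(sumstats)
        self.panel = panel
        self.pred_size = pred_size
        self.flank_size = flank_size
        self.lam = lam
        self.min_r2pred = min_r2pred
        self.keep_ambiguous = keep_ambiguous
        self.rescale = rescale

    @classmethod
    def from_files(
        cls,
        sumstats_path,
        vcf=None,
        hap=None,
        legend=None,
        region=None,
        chrom: str = "1",
        column_map=None,
        maf_min: float = 0.005,
        **params,
    ) -> "DirectImputation":
        """Build the model from a summary-statistics file and a panel file
        (either ``vcf``, or ``hap`` + ``legend``)."""
        from .panel import load_hap_legend, load_vcf_panel

        records = read_sumstats(sumstats_path, column_map=column_map)
        if vcf is not None:
            panel = load_vcf_panel(vcf, region=region, maf_min=maf_min)
        elif hap is not None and legend is not None:
            panel = load_hap_legend(hap, legend, chrom=chrom, maf_min=maf_min)
        else:
            raise ImputationError("provide either vcf= or hap= and legend=")
        return cls(records, panel, **params)

    def fit(self, corr_cache=None) -> "ImputationResults":
        """Harmonise, plan windows and impute; returns the results object."""
        hset = harmonize(self.sumstats, self.panel, keep_ambiguous=self.keep_ambiguous)
        windows = plan_windows(hset, self.pred_size, self.flank_size)
        records = impute_all(
            hset, self.panel,
            pred_size=self.pred_size, flank_size=self.flank_size,
            lam=self.lam, min_r2pred=self.min_r2pred, rescale=self.rescale,
            corr_cache=corr_cache, windows=windows,
        )
        return ImputationResults(self, hset, windows, records)

    def params_dict(self) -> dict:
        return {
            "pred_size": self.pred_size, "flank_size": self.flank_size,
            "lam": self.lam, "min_r2pred": self.min_r2pred,
            "keep_ambiguous": self.keep_ambiguous, "rescale": self.rescale,
        }


class ImputationResults:
    """Results of a :class:`DirectImputation` fit.

    Attributes
    ----------
    records : list of ImputedRecord
        All panel variants in position order (typed pass-through, imputed,
        or skipped).
    harmonization : HarmonizedSet
        The alignment bookkeeping (flip classes, off-panel count).
    windows : list of ImputationWindow
        The window plan used.
    """

    def __init__(self, model, hset, windows, records) -> None:
        self.model = model
        self.harmonization = hset
        self.windows = windows
        self.records = records

    def frame(self) -> pd.DataFrame:
        """Results as a DataFrame (one row per panel variant)."""
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "a1": [r.a1 for r in self.records],
                "a2": [r.a2 for r in self.records],
                "z": [r.z_imp for r in self.records],
                "p": [r.p for r in self.records],
                "r2pred": [r.r2pred for r in self.records],
                "n_typed_used": [r.n_typed_used for r in self.records],
                "status": [r.status for r in self.records],
            }
        )

    def counts(self) -> dict[str, int]:
        c: dict[str, int] = {"typed": 0, "imputed": 0, "skipped": 0}
        for r in self.records:
            c[r.status] = c.get(r.status, 0) + 1
        return c

    def summary(self) -> str:
        """Plain-text summary: parameters, counts, r2pred quantiles."""
        c = self.counts()
        imp_r2 = np.array([r.r2pred for r in self.records if r.status != "typed"])
        lines = [
            "Direct summary-statistic imputation",
            "=" * 47,
            f"panel variants       {self.harmonization.panel.n_variant:>10d}",
            f"reference haplotypes {self.harmonization.panel.n_hap:>10d}",
            f"typed                {c['typed']:>10d}",
            f"imputed              {c['imputed']:>10d}",
            f"skipped (low r2pred) {c['skipped']:>10d}",
            f"off-panel records    {self.harmonization.n_ignored:>10d}",
            f"windows              {len(self.windows):>10d}",
            "-" * 47,
        ]
        for k, v in self.model.params_dict().items():
            lines.append(f"{k:<21}{v!s:>26}")
        if imp_r2.size:
            q = np.percentile(imp_r2, [0, 25, 50, 75, 100])
            lines.append("-" * 47)
            lines.append(
                "r2pred (targets)     "
                + " ".join(f"{x:.3f}" for x in q)
                + "  (min q25 med q75 max)"
            )
        lines.append("=" * 47)
        return "\n".join(lines)

    def save(self, path, extra_header: dict | None = None) -> None:
        """Write the results table (with a parameter-recording header)."""
        hdr = {"tool": f"zimpute {_pkg_version}",
               "panel_checksum": self.harmonization.panel.checksum()}
        hdr.update(self.model.params_dict())
        if extra_header:
            hdr.update(extra_header)
        write_results(
            self.records, path, header_lines=[f"{k}={v}" for k, v in hdr.items()]
        )
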