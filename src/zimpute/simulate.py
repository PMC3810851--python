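"""Synthetic quantitative-trait GWAS data with block LD.

The generator emulates the statistical structure of a summary-statistic
imputation accuracy experiment: a phased reference panel with block-wise LD,
a study population drawn from the same haplotype pool (so study and
reference LD match by construction), a quantitative phenotype driven by a
small set of causal SNPs, single-SNP association Z-scores, and
missing-at-random masking of typed SNPs whose held-out Z-scores are the
truth against which imputation is scored.

Haplotypes are built as mosaics of a few founder haplotypes with shared
recombination breakpoints: founder alleles are drawn independently per site
with U-shaped allele frequencies; each site starts a new LD block with
probability ``ld_decay`` (human recombination is concentrated at shared
hotspots, which is what makes LD blocky); within a block every haplotype
copies a single founder, re-drawn uniformly at each block start; a small
per-allele mutation rate keeps within-block correlations just below 1.
``ld_decay -> 1`` gives independent sites; ``ld_decay = 0`` makes every
haplotype a (mutated) copy of one founder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .harmonize import harmonize
from .impute import DirectImputation
from .panel import ReferencePanel, corr_block
from .sumstats import SumStatRecord

log = logging.getLogger(__name__)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]

#: Site span (bp) between adjacent simulated SNPs.
_POS_STEP = 500

#: Band (in SNPs) within which proxy LD is scanned for threshold masking.
_PROXY_BAND = 50


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of one simulated accuracy experiment.

    Defaults describe the standard desk-scale setup: a 1,000-haplotype
    reference over 2,000 SNPs with block LD, 2,000 study subjects drawn from
    the panel pool, 10 causal SNPs explaining 30% of phenotypic variance,
    and 5% of SNPs masked at random.
    """

    n_hap: int = 1000
    n_snp: int = 2000
    n_subj: int = 2000
    n_causal: int = 10
    h2: float = 0.3
    mask: float | Sequence[int] = 0.05
    mask_ld_threshold: float | None = None
    n_founder: int = 2
    ld_decay: float = 0.175
    mut_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 < 1.0):
            raise SimulationError("h2 must be in (0, 1)")
        if self.n_causal > self.n_snp:
            raise SimulationError("n_causal cannot exceed n_snp")
        if isinstance(self.mask, float) and not (0.0 < self.mask < 1.0):
            raise SimulationError("mask fraction must be in (0, 1)")
        if not (0.0 <= self.ld_decay <= 1.0):
            raise SimulationError("ld_decay must be in [0, 1]")
        if not (0.0 <= self.mut_rate < 0.5):
            raise SimulationError("mut_rate must be in [0, 0.5)")
        if self.n_founder < 2:
            raise SimulationError("need n_founder >= 2")


@dataclass
class SimResult:
    """One simulated dataset ready for imputation and scoring."""

    panel: ReferencePanel
    true_z: np.ndarray
    observed: list[SumStatRecord]
    truth_at_masked: dict[tuple[str, int], float]
    masked_idx: np.ndarray
    genotypes: np.ndarray | None = None
    phenotype: np.ndarray | None = None


def simulate_panel(cfg: SimConfig, rng: np.random.Generator | None = None) -> ReferencePanel:
    """Generate the reference haplotype panel (block-mosaic model).

    Founder alleles are Bernoulli with per-site frequencies from a U-shaped
    distribution on (0.01, 0.5) (redrawn at sites where all founders agree,
    so every site is polymorphic among founders).  Each site opens a new LD
    block with probability ``ld_decay``; block boundaries are shared by all
    haplotypes (hotspot recombination), and every haplotype copies one
    uniformly chosen founder throughout a block.  Each allele is then
    flipped with probability ``mut_rate``.  Deterministic given the seed.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    K, n_snp, n_hap = cfg.n_founder, cfg.n_snp, cfg.n_hap
    freqs = 0.01 + 0.49 * rng.beta(0.5, 0.5, size=n_snp)
    founders = (rng.random((K, n_snp)) < freqs).astype(np.uint8)
    # redraw monomorphic founder columns so the pool is polymorphic everywhere
    for _ in range(1000):
        mono = np.flatnonzero(founders.min(0) == founders.max(0))
        if mono.size == 0:
            break
        founders[:, mono] = (
            rng.random((K, mono.size)) < freqs[mono]
        ).astype(np.uint8)
    else:  # pragma: no cover - only reachable with pathological frequencies
        raise SimulationError("could not generate polymorphic founder sites")

    is_start = rng.random(n_snp) < cfg.ld_decay
    is_start[0] = True
    block_of = np.cumsum(is_start) - 1  # site -> block index
    n_block = int(block_of[-1]) + 1
    founder_of = rng.integers(0, K, size=(n_hap, n_block))
    path = founder_of[:, block_of]  # (n_hap, n_snp)
    H = founders[path, np.arange(n_snp)]
    if cfg.mut_rate > 0:
        H = np.where(rng.random(H.shape) < cfg.mut_rate, 1 - H, H)
    # mutation cannot silence a site, but a block may by chance use one
    # founder only; flip one allele at any such site
    mono = np.flatnonzero(H.min(0) == H.max(0))
    if mono.size:
        H[rng.integers(0, n_hap, size=mono.size), mono] ^= 1

    pair_ix = rng.integers(0, len(_ALLELE_PAIRS), size=n_snp)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_ix], dtype=object)
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_ix], dtype=object)
    return ReferencePanel(
        chrom=np.array(["1"] * n_snp, dtype=object),
        pos=10001 + _POS_STEP * np.arange(n_snp, dtype=np.int64),
        ref=ref, alt=alt, H=H,
    )


def simulate_study(
    panel: ReferencePanel, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw study genotypes from the panel pool and simulate the phenotype.

    Each subject's genotype is the sum of two haplotypes drawn uniformly
    (with replacement) from the panel, so study LD matches reference LD by
    construction.  The phenotype is ``sum_j beta_j g_j + noise`` with the
    causal effects scaled so they jointly explain ``h2`` of the phenotypic
    variance.

    Returns ``(genotypes, phenotype, betas)`` with ``betas`` dense over all
    SNPs (zero at non-causal sites).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    hap_ix = rng.integers(0, panel.n_hap, size=(cfg.n_subj, 2))
    G = (panel.H[hap_ix[:, 0], :] + panel.H[hap_ix[:, 1], :]).astype(np.float64)
    causal = rng.choice(panel.n_variant, size=cfg.n_causal, replace=False)
    beta_raw = rng.normal(size=cfg.n_causal)
    g = G[:, causal] @ beta_raw
    v = g.var()
    if v <= 0:
        raise SimulationError("causal genotypes carry no variance; reseed")
    scale = np.sqrt(cfg.h2 / v)
    y = g * scale + rng.normal(0.0, np.sqrt(1.0 - cfg.h2), size=cfg.n_subj)
    betas = np.zeros(panel.n_variant)
    betas[causal] = beta_raw * scale
    return G, y, betas


def gwas_z(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Single-SNP association Z-scores from simple linear regression.

    For each SNP, the Wald statistic ``t = r sqrt((n-2)/(1-r^2))`` of the
    dosage-phenotype correlation ``r`` is mapped through the Student-t to
    standard-normal quantile correspondence (exact tail mapping, stable for
    extreme statistics).  The sign follows the alt-allele effect direction.
    SNPs with zero dosage variance are flagged with NaN and excluded.
    """
    G = np.asarray(G, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = G.shape[0]
    if n < 3:
        raise SimulationError("need at least 3 subjects")
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sg = np.sqrt((Gc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    bad = sg == 0
    if bad.any():
        log.warning("%d zero-variance SNP(s); Z set to NaN", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Gc.T @ yc) / (sg * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    # exact t -> N(0,1) quantile map via log upper-tail probabilities
    z = np.sign(t) * -special.ndtri_exp(stats.t.logsf(np.abs(t), df))
    z = np.where(np.isfinite(z), z, np.sign(r) * 40.0)  # |r| ~= 1 edge
    z[bad] = np.nan
    return z


def mask_and_package(
    z_all: np.ndarray,
    panel: ReferencePanel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    genotypes: np.ndarray | None = None,
    phenotype: np.ndarray | None = None,
) -> SimResult:
    """Hold out a set of SNPs' Z-scores as imputation targets.

    The mask is either an explicit list of variant indices, or a
    missing-at-random fraction; with ``cfg.mask_ld_threshold`` set, a SNP is
    maskable only while it retains a typed proxy with abs(r) at or above the
    threshold (scanned within a local band), and masking never strands a
    previously masked SNP without a proxy.  Selection is deterministic given
    the generator state.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    valid = np.flatnonzero(np.isfinite(z_all))
    if valid.size == 0:
        raise SimulationError("no SNPs with defined Z")

    if not isinstance(cfg.mask, float):
        masked = np.asarray(sorted(cfg.mask), dtype=np.intp)
        if not set(masked.tolist()) <= set(valid.tolist()):
            raise SimulationError("mask list contains SNPs with undefined Z")
    else:
        n_mask = int(round(cfg.mask * valid.size))
        if cfg.mask_ld_threshold is None:
            masked = np.sort(rng.choice(valid, size=n_mask, replace=False))
        else:
            masked = _threshold_mask(panel, valid, n_mask, cfg.mask_ld_threshold, rng)
    if masked.size >= valid.size:
        raise SimulationError("mask would remove all typed SNPs")

    masked_set = set(masked.tolist())
    observed = [
        SumStatRecord(
            chrom=panel.chrom[i], pos=int(panel.pos[i]),
            a1=panel.alt[i], a2=panel.ref[i], z=float(z_all[i]),
        )
        for i in valid
        if i not in masked_set
    ]
    truth = {
        (panel.chrom[i], int(panel.pos[i])): float(z_all[i]) for i in masked
    }
    return SimResult(
        panel=panel, true_z=z_all, observed=observed,
        truth_at_masked=truth, masked_idx=masked,
        genotypes=genotypes, phenotype=phenotype,
    )


def _banded_neighbors(
    panel: ReferencePanel, threshold: float, band: int = _PROXY_BAND
) -> dict[int, set[int]]:
    """Per-SNP sets of neighbours with |r| >= threshold within +/- band sites."""
    Xs = panel.standardized()
    n = panel.n_variant
    nb: dict[int, set[int]] = {j: set() for j in range(n)}
    for d in range(1, min(band, n - 1) + 1):
        r = (Xs[:, d:] * Xs[:, :-d]).mean(axis=0)
        for j in np.flatnonzero(np.abs(r) >= threshold):
            nb[j].add(j + d)
            nb[j + d].add(j)
    return nb


def _threshold_mask(
    panel: ReferencePanel,
    valid: np.ndarray,
    n_mask: int,
    threshold: float,
    rng: np.random.Generator,
) -> np.ndarray:
    nb_all = _banded_neighbors(panel, threshold)
    valid_set = set(valid.tolist())
    nb = {j: nb_all[j] & valid_set for j in valid}
    maskable = [j for j in valid if nb[j]]
    if not maskable:
        raise SimulationError(
            f"no SNP has a typed proxy with |r| >= {threshold}; nothing maskable"
        )
    retained = set(valid.tolist())
    cnt: dict[int, int] = {}  # retained-proxy count per masked SNP
    masked: list[int] = []
    for j in rng.permutation(np.array(maskable, dtype=np.intp)):
        j = int(j)
        if len(masked) == n_mask:
            break
        proxies = [x for x in nb[j] if x in retained and x != j]
        if not proxies:
            continue
        if any(cnt[m] == 1 and j in nb[m] for m in masked):
            continue
        retained.discard(j)
        for m in masked:
            if j in nb[m]:
                cnt[m] -= 1
        cnt[j] = len(proxies)
        masked.append(j)
    if len(masked) < n_mask:
        log.warning("only %d of %d requested SNPs were maskable", len(masked), n_mask)
    if not masked:
        raise SimulationError("threshold masking produced an empty mask")
    return np.sort(np.array(masked, dtype=np.intp))


def evaluate_accuracy(
    imputed_records, truth: Mapping[tuple[str, int], float]
) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation between imputed and true Z-scores.

    Scores records with status ``imputed`` whose (chrom, pos) appears in
    ``truth``.  Returns the pooled r-squared and a per-SNP table with
    absolute errors.  Note the metric is invariant to affine shifts of the
    imputed values; it measures ranking/scaling agreement, not bias.
    """
    rows = []
    for rec in imputed_records:
        key = (rec.chrom, rec.pos)
        if key in truth and rec.status == "imputed" and rec.z_imp is not None:
            rows.append(
                (rec.chrom, rec.pos, rec.z_imp, truth[key],
                 abs(rec.z_imp - truth[key]), rec.r2pred)
            )
    if len(rows) < 2:
        raise SimulationError("need at least 2 scored SNPs to compute r2")
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "z_imp", "z_true", "abs_err", "r2pred"]
    )
    r = np.corrcoef(table["z_imp"], table["z_true"])[0, 1]
    return float(r**2), table


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Panel -> study -> Z-scores -> masking, with one seeded generator."""
    rng = np.random.default_rng(cfg.seed)
    panel = simulate_panel(cfg, rng)
    G, y, _ = simulate_study(panel, cfg, rng)
    z = gwas_z(G, y)
    return mask_and_package(z, panel, cfg, rng, genotypes=G, phenotype=y)


def accuracy_experiment(
    cfg: SimConfig,
    n_reps: int = 25,
    base_seed: int = 0,
    **fit_params,
) -> dict:
    """Replicate the accuracy experiment and pool imputed-vs-true Z pairs.

    Each replicate ``r`` reruns :func:`simulate_experiment` with seed
    ``base_seed + r``, fits :class:`~zimpute.impute.DirectImputation` with
    ``fit_params`` (defaults otherwise) on the observed statistics, and
    collects (imputed, true) pairs at the masked SNPs.  Returns the pooled
    squared correlation, the per-replicate values, and the pair count.
    """
    pairs_imp: list[np.ndarray] = []
    pairs_true: list[np.ndarray] = []
    per_rep = []
    n_skipped = 0
    for r in range(n_reps):
        sim = simulate_experiment(replace(cfg, seed=base_seed + r))
        model = DirectImputation(sim.observed, sim.panel, **fit_params)
        res = model.fit()
        r2, table = evaluate_accuracy(res.records, sim.truth_at_masked)
        n_skipped += len(sim.truth_at_masked) - len(table)
        per_rep.append(r2)
        pairs_imp.append(table["z_imp"].to_numpy())
        pairs_true.append(table["z_true"].to_numpy())
    zi = np.concatenate(pairs_imp)
    zt = np.concatenate(pairs_true)
    pooled = float(np.corrcoef(zi, zt)[0, 1] ** 2)
    return {
        "r2_pooled": pooled,
        "r2_per_rep": per_rep,
        "n_pairs": int(zi.size),
        "n_skipped": n_skipped,
        "z_imp": zi,
        "z_true": zt,
    }


def null_calibration(
    cfg: SimConfig, n_reps: int = 500, seed: int = 0, **fit_params
) -> pd.DataFrame:
    """Empirical null behaviour of imputed Z at masked SNPs.

    Fixes one simulated panel/study/mask, then repeatedly permutes the
    phenotype (destroying all genotype-phenotype association), recomputes
    Z-scores and reimputes.  Under the null each imputed Z should have mean
    ~0 and variance ~its r2pred.  Returns a per-masked-SNP table with the
    empirical mean, variance and r2pred.
    """
    sim = simulate_experiment(cfg)
    if sim.genotypes is None or sim.phenotype is None:
        raise SimulationError("simulation did not retain genotypes/phenotype")
    rng = np.random.default_rng(seed)
    panel = sim.panel
    masked = sim.masked_idx
    masked_keys = [(panel.chrom[i], int(panel.pos[i])) for i in masked]

    # window plan and correlation blocks are fixed across permutations
    model0 = DirectImputation(sim.observed, panel, **fit_params)
    res0 = model0.fit()
    cache = [(w.Stt, w.Sut) for w in res0.windows]
    r2pred = {
        (r.chrom, r.pos): r.r2pred for r in res0.records if (r.chrom, r.pos) in set(masked_keys)
    }

    draws = np.empty((n_reps, len(masked)))
    for rep in range(n_reps):
        y = rng.permutation(sim.phenotype)
        z = gwas_z(sim.genotypes, y)
        observed = [
            SumStatRecord(
                chrom=rec.chrom, pos=rec.pos, a1=rec.a1, a2=rec.a2,
                z=float(z[i]),
            )
            for rec, i in zip(sim.observed, _observed_indices(sim))
        ]
        res = DirectImputation(observed, panel, min_r2pred=0.0, **_drop(fit_params, "min_r2pred")).fit(
            corr_cache=cache
        )
        by_key = {(r.chrom, r.pos): r.z_imp for r in res.records}
        draws[rep] = [by_key[k] if by_key[k] is not None else np.nan for k in masked_keys]

    return pd.DataFrame(
        {
            "chrom": [k[0] for k in masked_keys],
            "pos": [k[1] for k in masked_keys],
            "mean": draws.mean(axis=0),
            "var": draws.var(axis=0, ddof=1),
            "r2pred": [r2pred.get(k, np.nan) for k in masked_keys],
            "n_reps": n_reps,
        }
    )


def _observed_indices(sim: SimResult) -> np.ndarray:
    pos_to_idx = {
        (c, int(p)): i for i, (c, p) in enumerate(zip(sim.panel.chrom, sim.panel.pos))
    }
    return np.array([pos_to_idx[(r.chrom, r.pos)] for r in sim.observed], dtype=np.intp)


def _drop(d: dict, key: str) -> dict:
    return {k: v for k, v in d.items() if k != key}


def save_truth(sim: SimResult, path) -> None:
    """Write the held-out true Z-scores (CHR, POS, Z_TRUE, tab-delimited)."""
    with open(path, "w") as fh:
        fh.write("CHR\tPOS\tZ_TRUE\n")
        for (c, p), z in sorted(sim.truth_at_masked.items(), key=lambda kv: kv[0][1]):
            fh.write(f"{c}\t{p}\t{z:.6g}\n")


def load_truth(path) -> dict[tuple[str, int], float]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str})
    return {
        (str(c), int(p)): float(z)
        for c, p, z in zip(df["CHR"], df["POS"], df["Z_TRUE"])
    }
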