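"""The three smoothing strategies that turn per-bin exact-test results into
posterior differential-methylation probabilities.

* **FHB** — binarise the per-bin FDR at a cut-off and treat the 0/1 calls as
  noisy observations of the hidden state; fit pi, A and the Bernoulli
  correctness probability by Baum-Welch, one chain per methylation site.
* **FHC** — skip the binarisation: row n of the emission matrix is
  (p_n, 1 - p_n), the exact-test p-value read as the likelihood of the bin
  under "no change" and "change". EM then re-estimates pi and A only.
* **FastFHC** — binarise as in FHB, estimate pi and A once from the pooled
  calls of *all* sites in a single counting pass, then run one E-step per
  site with the FHC emission rows. No iteration, so short sites need no
  per-site fit.

Sites with fewer bins than ``min_bins_for_em`` cannot support per-site EM;
FHB and FHC fall back to reporting 1 - p_value as a posterior surrogate and
flag those bins. FastFHC never needs the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contingency import LibrarySizes, test_bins
from .errors import ValidationError
from .hmm import (
    BaumWelchResult,
    FixedEmissionMatrix,
    HmmParams,
    baum_welch,
    estep_only,
    random_init,
)

STRATEGIES = ("fhb", "fhc", "fastfhc")


@dataclass
class StrategyConfig:
    """Knobs shared by the three strategies.

    fdr_threshold binarises the BH-adjusted p-values for FHB and FastFHC;
    posterior_cutoff is the default DMR-calling level; tol/max_iter/seed
    control EM; sites shorter than min_bins_for_em skip per-site EM;
    transition_pseudocount smooths the pooled FastFHC transition counts.
    """

    strategy: str = "fhc"
    fdr_threshold: float = 0.05
    posterior_cutoff: float = 0.9
    tol: float = 1e-6
    max_iter: int = 100
    seed: int = 0
    min_bins_for_em: int = 5
    transition_pseudocount: float = 1.0
    test_pseudocount: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValidationError("fdr_threshold must lie in (0, 1)")
        if not (0.0 < self.posterior_cutoff < 1.0):
            raise ValidationError("posterior_cutoff must lie in (0, 1)")


@dataclass(frozen=True)
class PooledParams:
    """Genome-wide initial distribution and transition matrix (FastFHC)."""

    pi: np.ndarray
    A: np.ndarray


@dataclass
class DetectionResult:
    """Per-bin posterior track plus the fitted parameters that produced it."""

    bins: pd.DataFrame
    strategy: str
    site_params: dict[str, HmmParams] = field(default_factory=dict)
    pooled: PooledParams | None = None


def binarize(fdr: np.ndarray, threshold: float) -> np.ndarray:
    """0/1 observation sequence: 1 iff the adjusted p-value beats the cut-off."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie in (0, 1)")
    return (np.asarray(fdr, dtype=float) < threshold).astype(np.int64)


def build_emission_from_pvalues(p_values: np.ndarray) -> FixedEmissionMatrix:
    """Emission rows (p_n, 1 - p_n): the p-value as the likelihood of state 0."""
    p = np.asarray(p_values, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return FixedEmissionMatrix(np.column_stack([p, 1.0 - p]))


def estimate_pooled_params(
    sequences: list[np.ndarray], pseudocount: float = 1.0
) -> PooledParams:
    """Single-pass pi/A estimate from binary calls pooled over all sites.

    pi = (1 - fraction of DMS bins, fraction of DMS bins) over every bin;
    transitions are counted within sites only and smoothed additively:
    A[i, j] = (count(i->j) + pseudocount) / (count(i->.) + 2*pseudocount).
    """
    total = sum(int(np.asarray(s).size) for s in sequences)
    if total == 0:
        raise ValidationError("cannot pool parameters from zero bins")
    ones = sum(int(np.asarray(s).sum()) for s in sequences)
    frac = ones / total

    counts = np.zeros((2, 2))
    for s in sequences:
        s = np.asarray(s)
        if s.size < 2:
            continue
        a, b = s[:-1], s[1:]
        for i in range(2):
            for j in range(2):
                counts[i, j] += int(np.sum((a == i) & (b == j)))

    A = np.empty((2, 2))
    for i in range(2):
        denom = counts[i].sum() + 2.0 * pseudocount
        if denom > 0:
            A[i] = (counts[i] + pseudocount) / denom
        else:  # no transitions observed and no smoothing: fall back to uniform
            A[i] = 0.5
    return PooledParams(pi=np.array([1.0 - frac, frac]), A=A)


def _site_rngs(seed: int, site_ids: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(site_ids))
    return {sid: np.random.default_rng(ss) for sid, ss in zip(site_ids, children)}


def _iter_sites(results: pd.DataFrame):
    for site_id, grp in results.groupby("site_id", sort=False):
        yield str(site_id), grp


def _smooth_fhb(results: pd.DataFrame, cfg: StrategyConfig) -> DetectionResult:
    posterior = np.empty(len(results))
    fallback = np.zeros(len(results), dtype=bool)
    site_params: dict[str, HmmParams] = {}
    site_ids = [sid for sid, _ in _iter_sites(results)]
    rngs = _site_rngs(cfg.seed, site_ids)

    pos = 0
    for site_id, grp in _iter_sites(results):
        n = len(grp)
        sl = slice(pos, pos + n)
        pos += n
        if n < cfg.min_bins_for_em:
            posterior[sl] = 1.0 - grp["p_value"].to_numpy()
            fallback[sl] = True
            continue
        obs = binarize(grp["fdr"].to_numpy(), cfg.fdr_threshold)
        init = random_init(rngs[site_id])
        fit = baum_welch(init, obs, max_iter=cfg.max_iter, tol=cfg.tol)
        posterior[sl] = fit.track.gamma1
        site_params[site_id] = fit.params

    bins = results.copy()
    bins["posterior"] = posterior
    bins["em_fallback"] = fallback
    return DetectionResult(bins=bins, strategy="fhb", site_params=site_params)


def _smooth_fhc(results: pd.DataFrame, cfg: StrategyConfig) -> DetectionResult:
    posterior = np.empty(len(results))
    fallback = np.zeros(len(results), dtype=bool)
    site_params: dict[str, HmmParams] = {}
    site_ids = [sid for sid, _ in _iter_sites(results)]
    rngs = _site_rngs(cfg.seed, site_ids)

    pos = 0
    for site_id, grp in _iter_sites(results):
        n = len(grp)
        sl = slice(pos, pos + n)
        pos += n
        if n < cfg.min_bins_for_em:
            posterior[sl] = 1.0 - grp["p_value"].to_numpy()
            fallback[sl] = True
            continue
        emission = build_emission_from_pvalues(grp["p_value"].to_numpy())
        init = random_init(rngs[site_id], emission=emission)
        fit: BaumWelchResult = baum_welch(init, max_iter=cfg.max_iter, tol=cfg.tol)
        posterior[sl] = fit.track.gamma1
        site_params[site_id] = fit.params

    bins = results.copy()
    bins["posterior"] = posterior
    bins["em_fallback"] = fallback
    return DetectionResult(bins=bins, strategy="fhc", site_params=site_params)


def _smooth_fastfhc(results: pd.DataFrame, cfg: StrategyConfig) -> DetectionResult:
    calls = [
        binarize(grp["fdr"].to_numpy(), cfg.fdr_threshold)
        for _, grp in _iter_sites(results)
    ]
    pooled = estimate_pooled_params(calls, cfg.transition_pseudocount)

    posterior = np.empty(len(results))
    pos = 0
    for _, grp in _iter_sites(results):
        n = len(grp)
        emission = build_emission_from_pvalues(grp["p_value"].to_numpy())
        params = HmmParams(pi=pooled.pi, A=pooled.A, emission=emission)
        posterior[pos : pos + n] = estep_only(params).gamma1
        pos += n

    bins = results.copy()
    bins["posterior"] = posterior
    bins["em_fallback"] = False
    return DetectionResult(bins=bins, strategy="fastfhc", pooled=pooled)


_SMOOTHERS = {"fhb": _smooth_fhb, "fhc": _smooth_fhc, "fastfhc": _smooth_fastfhc}


def smooth_results(results: pd.DataFrame, cfg: StrategyConfig) -> DetectionResult:
    """Apply one strategy to a table that already carries p_value/fdr columns."""
    for col in ("p_value", "fdr"):
        if col not in results.columns:
            raise ValidationError(f"results table lacks the {col!r} column")
    return _SMOOTHERS[cfg.strategy](results, cfg)


def run_fhb(table: pd.DataFrame, sizes: LibrarySizes, cfg: StrategyConfig) -> DetectionResult:
    """Exact tests, FDR binarisation, per-site Baum-Welch with Bernoulli emission."""
    return _smooth_fhb(test_bins(table, sizes, cfg.test_pseudocount), cfg)


def run_fhc(table: pd.DataFrame, sizes: LibrarySizes, cfg: StrategyConfig) -> DetectionResult:
    """Exact tests, p-value emission rows, per-site EM on pi and A only."""
    return _smooth_fhc(test_bins(table, sizes, cfg.test_pseudocount), cfg)


def run_fastfhc(
    table: pd.DataFrame, sizes: LibrarySizes, cfg: StrategyConfig
) -> DetectionResult:
    """Exact tests, pooled single-pass pi/A estimate, one E-step per site."""
    return _smooth_fastfhc(test_bins(table, sizes, cfg.test_pseudocount), cfg)


def detect(table: pd.DataFrame, sizes: LibrarySizes, cfg: StrategyConfig) -> DetectionResult:
    """Dispatch on ``cfg.strategy``."""
    return smooth_results(test_bins(table, sizes, cfg.test_pseudocount), cfg)


def call_dmrs(result: DetectionResult, cutoff: float = 0.9) -> pd.DataFrame:
    """Merge consecutive bins with posterior >= cutoff into DMR intervals.

    Returns one row per DMR with site_id, dmr_id, first/last bin index
    (inclusive), n_bins, mean/min posterior, the best (smallest) bin
    p-value, a +/-1 direction from the sign of the summed finite log2 odds
    ratios (0 when uninformative), and genomic chrom/start/end when the
    input carried coordinates.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError("cutoff must lie in [0, 1]")
    bins = result.bins
    has_coords = (
        "chrom" in bins.columns
        and "start" in bins.columns
        and bins["start"].notna().all()
    )
    rows = []
    for site_id, grp in _iter_sites(bins):
        marked = grp["posterior"].to_numpy() >= cutoff
        if not marked.any():
            continue
        # boundaries of maximal runs of True
        padded = np.concatenate([[False], marked, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive
        for k, (a, b) in enumerate(zip(starts, ends), start=1):
            seg = grp.iloc[a:b]
            lors = seg["log2_or"].to_numpy(dtype=float) if "log2_or" in seg else np.array([])
            finite = lors[np.isfinite(lors)]
            signed = np.sign(finite.sum()) if finite.size else (
                np.sign(lors).sum() if lors.size else 0.0
            )
            row = {
                "site_id": site_id,
                "dmr_id": f"{site_id}.dmr_{k}",
                "bin_first": int(seg["bin_index"].iloc[0]),
                "bin_last": int(seg["bin_index"].iloc[-1]),
                "n_bins": int(b - a),
                "mean_posterior": float(seg["posterior"].mean()),
                "min_posterior": float(seg["posterior"].min()),
                "best_p": float(seg["p_value"].min()) if "p_value" in seg else np.nan,
                "direction": int(signed) if signed else 0,
            }
            if has_coords:
                row["chrom"] = seg["chrom"].iloc[0]
                row["start"] = int(seg["start"].iloc[0])
                row["end"] = int(seg["end"].iloc[-1])
                row["strand"] = seg["strand"].iloc[0] if "strand" in seg else "."
            rows.append(row)
    return pd.DataFrame(rows)
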