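"""Per-bin differential methylation testing on MeRIP-Seq counts.

Each bin carries four read counts: untreated input (x0), untreated IP (y0),
treated input (x1) and treated IP (y1), drawn from libraries of depth
N0, M0, N1, M1. Conditioning the Poisson count model on the per-condition
totals reduces the comparison of methylation proportions to a test of
independence in the 2x2 table (x0, y0 | x1, y1) — but only once the depths
satisfy N1*M0 == N0*M1. We therefore rescale exactly one sample (the treated
IP) to establish that balance and then apply a two-tailed Fisher's exact
test: under the null, x0 is hypergeometric with population N = x0+y0+x1+y1,
draws n = x0+y0 and category size K = x0+x1.

The two-sided p-value follows the minimum-likelihood rule: sum the
hypergeometric masses of every outcome no more probable than the observed
one (with a 1e-7 relative slack on the comparison, the convention shared by
the classical implementations of the exact test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

#: relative slack when comparing point masses in the two-sided rule
REL_TOL = 1e-7

_COUNT_COLS = ("x0", "y0", "x1", "y1")


@dataclass(frozen=True)
class LibrarySizes:
    """Sequencing depths of the four libraries.

    Attributes
    ----------
    n0, n1 : float
        Input (background) library depths, untreated and treated.
    m0, m1 : float
        IP (methylation-enriched) library depths, untreated and treated.
    """

    n0: float
    n1: float
    m0: float
    m1: float

    def __post_init__(self) -> None:
        for name in ("n0", "n1", "m0", "m1"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"library size {name!r} must be a positive finite number, got {v}"
                )

    @classmethod
    def from_string(cls, spec: str) -> "LibrarySizes":
        """Parse ``"N0,N1,M0,M1"`` as written on the command line."""
        parts = spec.split(",")
        if len(parts) != 4:
            raise ValidationError(
                f"expected 4 comma-separated library sizes N0,N1,M0,M1, got {spec!r}"
            )
        try:
            n0, n1, m0, m1 = (float(p) for p in parts)
        except ValueError as exc:
            raise ValidationError(f"non-numeric library size in {spec!r}") from exc
        return cls(n0, n1, m0, m1)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.n0, self.n1, self.m0, self.m1)


def rescale_for_balance(
    x0: np.ndarray,
    y0: np.ndarray,
    x1: np.ndarray,
    y1: np.ndarray,
    sizes: LibrarySizes,
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray], LibrarySizes, float]:
    """Rescale the treated IP sample so that N1*M0 == N0*M1.

    Exactly one sample is touched: the treated IP depth becomes
    ``M1' = N1*M0/N0`` and its counts are multiplied by
    ``rho = M1'/M1 = N1*M0/(N0*M1)`` and rounded to the nearest integer
    (floored at zero). The other three samples pass through unchanged.

    Returns
    -------
    (counts, effective_sizes, rho)
        ``counts`` is the integer 4-tuple ``(x0, y0, x1, y1')``;
        ``effective_sizes`` satisfies the balance identity exactly.
    """
    rho = sizes.n1 * sizes.m0 / (sizes.n0 * sizes.m1)
    m1_new = sizes.n1 * sizes.m0 / sizes.n0
    x0 = np.asarray(x0, dtype=np.int64)
    y0 = np.asarray(y0, dtype=np.int64)
    x1 = np.asarray(x1, dtype=np.int64)
    y1_scaled = np.maximum(np.rint(np.asarray(y1, dtype=float) * rho), 0.0)
    y1_new = y1_scaled.astype(np.int64)
    eff = LibrarySizes(sizes.n0, sizes.n1, sizes.m0, m1_new)
    return (x0, y0, x1, y1_new), eff, rho


def two_tailed_pvalues(
    x0: np.ndarray,
    y0: np.ndarray,
    x1: np.ndarray,
    y1: np.ndarray,
    chunk: int = 1024,
) -> np.ndarray:
    """Vectorised two-tailed hypergeometric p-values for many 2x2 tables.

    Counts must already be on a depth-balanced scale. The hypergeometric
    mass over the whole support of each table is built from a single
    log-pmf anchor plus the exact ratio recurrence
    ``pmf(k+1)/pmf(k) = (K-k)(n-k) / ((k+1)(N-K-n+k+1))`` accumulated in
    log space, so one scipy call per table covers any support size.
    All-zero tables yield p = 1.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=np.int64))
    y0 = np.atleast_1d(np.asarray(y0, dtype=np.int64))
    x1 = np.atleast_1d(np.asarray(x1, dtype=np.int64))
    y1 = np.atleast_1d(np.asarray(y1, dtype=np.int64))
    if np.any(x0 < 0) or np.any(y0 < 0) or np.any(x1 < 0) or np.any(y1 < 0):
        raise ValidationError("negative count passed to two_tailed_pvalues")

    N = x0 + y0 + x1 + y1
    n = x0 + y0
    K = x0 + x1
    k_obs = x0

    out = np.ones(N.shape[0], dtype=float)
    (idx,) = np.nonzero(N > 0)
    log_slack = np.log1p(REL_TOL)

    for lo in range(0, idx.size, chunk):
        sel = idx[lo : lo + chunk]
        Nc, nc, Kc, kc = N[sel], n[sel], K[sel], k_obs[sel]
        kmin = np.maximum(0, nc + Kc - Nc)
        kmax = np.minimum(nc, Kc)
        L = int((kmax - kmin).max()) + 1
        kk = kmin[:, None] + np.arange(L)  # (B, L) candidate k values
        valid = kk <= kmax[:, None]

        lp_anchor = hypergeom.logpmf(kmin, Nc, Kc, nc)
        if L > 1:
            kt = kk[:, :-1].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                log_ratio = np.log((Kc[:, None] - kt) * (nc[:, None] - kt)) - np.log(
                    (kt + 1.0) * (Nc[:, None] - Kc[:, None] - nc[:, None] + kt + 1.0)
                )
            log_ratio = np.where(kk[:, :-1] < kmax[:, None], log_ratio, 0.0)
            logpmf = np.concatenate(
                [lp_anchor[:, None], lp_anchor[:, None] + np.cumsum(log_ratio, axis=1)],
                axis=1,
            )
        else:
            logpmf = lp_anchor[:, None]

        lp_obs = logpmf[np.arange(sel.size), kc - kmin]
        include = valid & (logpmf <= lp_obs[:, None] + log_slack)
        pv = np.where(include, np.exp(logpmf), 0.0).sum(axis=1)
        # deep tables can underflow the two-sided sum entirely; keep p > 0
        out[sel] = np.clip(pv, 1e-300, 1.0)

    return out


def fisher_exact_two_tailed(x0: int, y0: int, x1: int, y1: int) -> float:
    """Two-tailed exact p-value for one depth-balanced 2x2 count table."""
    return float(two_tailed_pvalues([x0], [y0], [x1], [y1])[0])


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_bins(
    table: pd.DataFrame, sizes: LibrarySizes, pseudocount: int = 0
) -> pd.DataFrame:
    """Per-bin rescaled Fisher's exact test with genome-wide BH FDR.

    Parameters
    ----------
    table
        Bin-count table with at least ``site_id, bin_index, x0, y0, x1, y1``,
        bins grouped by site and ordered by ``bin_index``.
    sizes
        The four library depths; the treated IP sample is rescaled to
        balance them before testing.
    pseudocount
        Optional integer added to all four (rescaled) counts of every bin.
        Default 0.

    Returns
    -------
    A copy of ``table`` with columns ``p_value``, ``fdr``, ``log2_or``
    (positive = hypermethylated in the treated condition; +/-inf for zero
    cells, NaN when undefined) and ``degenerate`` (all four counts zero).
    FDR is computed in one pass across all bins of all sites.
    """
    missing = [c for c in ("site_id", "bin_index", *_COUNT_COLS) if c not in table.columns]
    if missing:
        raise ValidationError(f"bin table is missing columns {missing}")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")

    (x0, y0, x1, y1), _, _ = rescale_for_balance(
        table["x0"].to_numpy(),
        table["y0"].to_numpy(),
        table["x1"].to_numpy(),
        table["y1"].to_numpy(),
        sizes,
    )
    degenerate = (x0 == 0) & (y0 == 0) & (x1 == 0) & (y1 == 0)
    if pseudocount:
        x0, y0, x1, y1 = (v + pseudocount for v in (x0, y0, x1, y1))

    p = two_tailed_pvalues(x0, y0, x1, y1)
    p[degenerate] = 1.0
    fdr = bh_fdr(p)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2_or = np.log2((x0 * y1).astype(float)) - np.log2((x1 * y0).astype(float))

    out = table.copy()
    out["p_value"] = p
    out["fdr"] = fdr
    out["log2_or"] = log2_or
    out["degenerate"] = degenerate
    return out
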