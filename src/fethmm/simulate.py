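"""Synthetic MeRIP-Seq four-sample bin counts with Markov ground truth.

One dataset is a set of RNA methylation sites, each split into ordered
adjacent bins. A two-state Markov chain (transition matrix ``a_sim``,
initial distribution ``pi_sim``) labels every bin as differentially
methylated (state 1) or not; counts are then drawn per bin:

    X0 ~ Poisson(N0 * lambda0)                              untreated input
    Y0 ~ Poisson(M0 * lambda0 * ip_scale)                   untreated IP
    X1 ~ Poisson(N1 * lambda0 * 2**d_g)                     treated input
    Y1 ~ Poisson(M1 * lambda0 * 2**d_g * ip_scale * shift)  treated IP

where ``d_g`` is a per-site differential-expression log2 fold change drawn
uniformly from ``de_log2fc_range`` (expression moves input and IP together)
and ``shift`` carries the per-bin methylation log2 odds ratio ``m_n``,
uniform on ``dm_log2or_range`` on state-1 bins and exactly 0 elsewhere.

Two readings of "odds ratio" are supported via ``dm_effect``:

* ``"count_odds_ratio"`` (default) — ``shift = 2**m``, so the expected odds
  ratio of the 2x2 read-count table (input/IP by condition) equals ``2**m``
  exactly.
* ``"proportion_odds_ratio"`` — the odds ratio acts on the within-peak
  methylation proportion ``eta0``: ``shift = odds_shift(m, eta0)`` with
  ``odds_shift(m) = [eta0 * 2**m / (1 - eta0 + eta0 * 2**m)] / eta0``.

Both leave the IP mean untouched at ``m = 0``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .contingency import LibrarySizes
from .errors import ValidationError


@dataclass
class SimConfig:
    """Generative settings for one synthetic dataset.

    Defaults give 100 sites of 1000 bins at depth 1e8 with normalised input
    Poisson mean 1e-6 (so ~100 reads per bin per sample), expression log2FC
    uniform on [-3, 3] per site, methylation log2 odds ratio uniform on
    [-3, 3] on differential bins, and self-transition probability 0.9.
    """

    n_sites: int = 100
    bins_per_site: int = 1000
    site_lengths: list[int] | None = None
    n0: float = 1e8
    n1: float = 1e8
    m0: float = 1e8
    m1: float = 1e8
    lambda0: float = 1e-6
    de_log2fc_range: tuple[float, float] = (-3.0, 3.0)
    dm_log2or_range: tuple[float, float] = (-3.0, 3.0)
    a_sim: tuple[tuple[float, float], tuple[float, float]] = ((0.9, 0.1), (0.1, 0.9))
    pi_sim: tuple[float, float] = (0.5, 0.5)
    eta0: float = 0.5
    ip_scale: float = 1.0
    dm_effect: str = "count_odds_ratio"

    def __post_init__(self) -> None:
        if self.dm_effect not in ("count_odds_ratio", "proportion_odds_ratio"):
            raise ValidationError(
                "dm_effect must be 'count_odds_ratio' or 'proportion_odds_ratio'"
            )
        if self.lambda0 <= 0:
            raise ValidationError("lambda0 must be positive")
        if not (0.0 < self.eta0 < 1.0):
            raise ValidationError("eta0 must lie in (0, 1)")
        for rng_ in (self.de_log2fc_range, self.dm_log2or_range):
            if rng_[0] > rng_[1]:
                raise ValidationError(f"range {rng_} is not ordered")
        A = np.asarray(self.a_sim, dtype=float)
        if A.shape != (2, 2) or np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1) > 1e-9):
            raise ValidationError("a_sim must be a 2x2 row-stochastic matrix")

    @property
    def sizes(self) -> LibrarySizes:
        return LibrarySizes(self.n0, self.n1, self.m0, self.m1)

    def lengths(self) -> list[int]:
        if self.site_lengths is not None:
            return [int(x) for x in self.site_lengths]
        return [self.bins_per_site] * self.n_sites

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        raw = json.loads(text)
        if "de_log2fc_range" in raw:
            raw["de_log2fc_range"] = tuple(raw["de_log2fc_range"])
        if "dm_log2or_range" in raw:
            raw["dm_log2or_range"] = tuple(raw["dm_log2or_range"])
        if "a_sim" in raw:
            raw["a_sim"] = tuple(tuple(r) for r in raw["a_sim"])
        if "pi_sim" in raw:
            raw["pi_sim"] = tuple(raw["pi_sim"])
        return cls(**raw)


@dataclass
class SimulatedDataset:
    """Counts plus the hidden truth that generated them."""

    table: pd.DataFrame
    states: list[np.ndarray]
    de_log2fc: np.ndarray  # one value per site
    dm_log2or: np.ndarray  # one value per bin, 0 on non-differential bins
    config: SimConfig = field(repr=False, default=None)

    @property
    def labels(self) -> np.ndarray:
        """Ground-truth state per bin, concatenated in table order."""
        return np.concatenate(self.states) if self.states else np.empty(0, dtype=np.int64)

    def truth_frame(self) -> pd.DataFrame:
        lengths = [s.size for s in self.states]
        return pd.DataFrame(
            {
                "site_id": self.table["site_id"].to_numpy(),
                "bin_index": self.table["bin_index"].to_numpy(),
                "state": self.labels,
                "dm_log2or": self.dm_log2or,
                "de_log2fc": np.repeat(self.de_log2fc, lengths),
            }
        )


def odds_shift(m: np.ndarray, eta0: float) -> np.ndarray:
    """Multiplier on the IP mean from applying odds ratio 2**m to eta0."""
    two_m = np.power(2.0, np.asarray(m, dtype=float))
    eta1 = eta0 * two_m / (1.0 - eta0 + eta0 * two_m)
    return eta1 / eta0


def _ip_shift(m: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.dm_effect == "count_odds_ratio":
        return np.power(2.0, np.asarray(m, dtype=float))
    return odds_shift(m, cfg.eta0)


def draw_states(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """One hidden 0/1 Markov chain per site, independent across sites."""
    A = np.asarray(cfg.a_sim, dtype=float)
    pi = np.asarray(cfg.pi_sim, dtype=float)
    out = []
    for n in cfg.lengths():
        u = rng.random(n)
        s = np.empty(n, dtype=np.int64)
        s[0] = 1 if u[0] < pi[1] else 0
        for t in range(1, n):
            s[t] = 1 if u[t] < A[s[t - 1], 1] else 0
        out.append(s)
    return out


def draw_counts(
    states: list[np.ndarray], cfg: SimConfig, rng: np.random.Generator
) -> SimulatedDataset:
    """Poisson counts for every bin given the hidden states."""
    lengths = np.array([s.size for s in states])
    n_sites = len(states)
    labels = np.concatenate(states) if states else np.empty(0, dtype=np.int64)
    n_bins = labels.size

    d = rng.uniform(*cfg.de_log2fc_range, size=n_sites)
    m = np.zeros(n_bins)
    dms = labels == 1
    m[dms] = rng.uniform(*cfg.dm_log2or_range, size=int(dms.sum()))

    d_per_bin = np.repeat(d, lengths)
    base = cfg.lambda0
    mu_x0 = np.full(n_bins, cfg.n0 * base)
    mu_y0 = np.full(n_bins, cfg.m0 * base * cfg.ip_scale)
    mu_x1 = cfg.n1 * base * np.power(2.0, d_per_bin)
    mu_y1 = cfg.m1 * base * cfg.ip_scale * np.power(2.0, d_per_bin) * _ip_shift(m, cfg)

    width = len(str(max(n_sites, 1)))
    site_ids = np.repeat(
        np.array([f"site_{i + 1:0{width}d}" for i in range(n_sites)]), lengths
    )
    bin_index = np.concatenate([np.arange(n) for n in lengths]) if n_sites else np.empty(0, int)

    table = pd.DataFrame(
        {
            "site_id": site_ids,
            "bin_index": bin_index,
            "x0": rng.poisson(mu_x0),
            "y0": rng.poisson(mu_y0),
            "x1": rng.poisson(mu_x1),
            "y1": rng.poisson(mu_y1),
        }
    )
    return SimulatedDataset(
        table=table, states=list(states), de_log2fc=d, dm_log2or=m, config=cfg
    )


def simulate_dataset(cfg: SimConfig, seed: int | np.random.SeedSequence) -> SimulatedDataset:
    """Draw hidden states then counts from one seeded generator."""
    rng = np.random.default_rng(seed)
    return draw_counts(draw_states(cfg, rng), cfg, rng)


def table1_config(**overrides) -> SimConfig:
    """The runtime/AUC benchmark setting: 7 sites of increasing length
    (50..350 bins) with self-transition probability 0.95."""
    base = SimConfig(
        site_lengths=[50, 100, 150, 200, 250, 300, 350],
        n_sites=7,
        a_sim=((0.95, 0.05), (0.05, 0.95)),
    )
    return replace(base, **overrides) if overrides else base


def table1_benchmark(
    seed: int,
    n_datasets: int = 10,
    cfg: SimConfig | None = None,
    strategy_cfg=None,
    methods: tuple[str, ...] = ("fhb", "fhc", "fastfhc", "raw"),
) -> pd.DataFrame:
    """Mean bin-level AUC of every method over repeated benchmark datasets.

    Returns a tidy frame (dataset, method, auc); average with
    ``df.groupby("method")["auc"].mean()``.
    """
    from .evaluate import evaluate_methods  # local import: evaluate also imports us

    cfg = cfg or table1_config()
    rows = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_datasets)):
        ds = simulate_dataset(cfg, child)
        aucs = evaluate_methods(ds, strategy_cfg=strategy_cfg, methods=methods)
        for method, auc in aucs.items():
            rows.append({"dataset": i, "method": method, "auc": auc})
    return pd.DataFrame(rows)
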