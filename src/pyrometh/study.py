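"""Replicate statistics and synthetic study scenarios.

Conditions (cell lines, drug treatments) are compared on LINE1 methylation
by two-sample Student's t-tests, either on total methylation (the mean
over CpG sites, the global-methylation readout) or independently per site
(focal methylation).  The scenario generator reproduces study conditions
end-to-end: per-replicate true fractions are drawn around the condition
means, a pyrogram is simulated with multiplicative peak noise, and the
replicate is quantified like a real run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .dispense import DispensationOrder, generate_dispensation
from .pyro import MethylationCall, quantify, simulate_pyrogram
from .seqcore import DegenerateSequence

#: The three-CpG LINE1 read-out used by the commercial global-methylation kit.
KIT_SEQUENCE_TO_ANALYZE = "TTYGTGGTGYGTYGTTT"
#: The kit's printed dispensation order (controls interleaved by the vendor).
KIT_DISPENSATION_ORDER = "GCTCGTGTAGTCAGTCG"

#: Default replicate-to-replicate spread of true per-site methylation
#: (percentage points) and default pyrogram peak noise (CV).  Chosen as a
#: realistic bisulfite-pyrosequencing run-to-run variability; the source
#: measurements report no dispersion, so both are configurable.
DEFAULT_SD = 3.0
DEFAULT_NOISE_CV = 0.05


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate methylation calls for one experimental condition."""

    condition: str
    replicates: tuple[MethylationCall, ...]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("a replicate set needs at least one replicate")
        sites = {c.n_sites for c in self.replicates}
        if len(sites) != 1:
            raise ValueError(f"replicates disagree on CpG site count: {sorted(sites)}")
        object.__setattr__(self, "replicates", tuple(self.replicates))

    @property
    def n(self) -> int:
        return len(self.replicates)

    @property
    def n_sites(self) -> int:
        return self.replicates[0].n_sites

    @property
    def site_matrix(self) -> np.ndarray:
        """(n, n_sites) array of per-site percentages."""
        return np.array([c.per_site_percent for c in self.replicates])

    @property
    def totals(self) -> np.ndarray:
        return np.array([c.total_percent for c in self.replicates])


def total_methylation(c: MethylationCall) -> float:
    """Total methylation of a call: arithmetic mean over its CpG sites."""
    return c.total_percent


@dataclass(frozen=True)
class ComparisonResult:
    label: str  # "total" or "site_<i>"
    t_statistic: float
    p_value: float
    group_means: tuple[float, float]
    n: tuple[int, int]
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _ttest(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float]:
    if np.var(x) == 0 and np.var(y) == 0:
        # degenerate: no within-group variability; equal means are simply equal
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_conditions(
    a: ReplicateSet,
    b: ReplicateSet,
    alpha: float = 0.05,
    scope: str = "total",
    equal_var: bool = True,
    bonferroni: bool = False,
) -> Union[ComparisonResult, tuple[ComparisonResult, ...]]:
    """Two-sided two-sample t-test between conditions.

    ``scope="total"`` tests total methylation and returns one result;
    ``scope="per_site"`` tests each CpG site independently and returns one
    result per site.  The default is Student's pooled-variance test;
    ``equal_var=False`` switches to Welch.  ``bonferroni`` scales the
    per-site significance level by the number of sites (off by default).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("need at least 2 replicates per group")
    if scope == "total":
        t, p = _ttest(a.totals, b.totals, equal_var)
        return ComparisonResult(
            label="total",
            t_statistic=t,
            p_value=p,
            group_means=(float(a.totals.mean()), float(b.totals.mean())),
            n=(a.n, b.n),
            alpha=alpha,
        )
    if scope == "per_site":
        if a.n_sites != b.n_sites:
            raise ValueError("conditions have different CpG site counts")
        level = alpha / a.n_sites if bonferroni else alpha
        out = []
        for i in range(a.n_sites):
            x, y = a.site_matrix[:, i], b.site_matrix[:, i]
            t, p = _ttest(x, y, equal_var)
            out.append(
                ComparisonResult(
                    label=f"site_{i + 1}",
                    t_statistic=t,
                    p_value=p,
                    group_means=(float(x.mean()), float(y.mean())),
                    n=(a.n, b.n),
                    alpha=level,
                )
            )
        return tuple(out)
    raise ValueError(f"unknown scope {scope!r}; use 'total' or 'per_site'")


# --- scenarios -------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A simulated study condition.

    ``per_site_means`` are the condition's true per-CpG methylation levels
    in percent; each replicate draws its true fractions from a Gaussian
    around them (sd in percentage points, truncated to [0, 1] as a
    fraction) and is then simulated and quantified end-to-end.
    """

    name: str
    per_site_means: tuple[float, ...]
    n: int
    sd: float = DEFAULT_SD
    noise_cv: float = DEFAULT_NOISE_CV
    template: str = KIT_SEQUENCE_TO_ANALYZE

    def __post_init__(self) -> None:
        if not self.per_site_means or any(
            not 0.0 <= x <= 100.0 for x in self.per_site_means
        ):
            raise ValueError("per-site means must lie in [0, 100]")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("scenarios need n >= 2 replicates")
        object.__setattr__(self, "per_site_means", tuple(self.per_site_means))


def _three_site(name: str, total: float, n: int) -> Scenario:
    return Scenario(name=name, per_site_means=(total,) * 3, n=n)


#: Built-in scenarios.  Control and treatment per-site means are the
#: measured values of the underlying study; cell-line conditions are known
#: only by their total methylation, applied uniformly across the kit's
#: three CpG sites; glioma means are configurable placeholders expressing
#: the reported direction (resistant lines hypomethylated vs parental).
SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        Scenario("positive_control", (86.0, 71.0, 77.0), n=5),
        Scenario("negative_control", (2.0, 2.0, 2.0), n=5),
        _three_site("nhdf", 56.0, n=5),
        _three_site("hek293", 53.0, n=3),
        _three_site("cka_ca", 51.0, n=3),
        _three_site("hacat", 49.0, n=5),
        Scenario("hacat_control", (53.0, 59.0, 63.0), n=6),
        Scenario("hacat_a_t2", (36.0, 40.0, 42.0), n=6),
        _three_site("glioma_parental", 60.0, n=4),
        _three_site("glioma_tmz_resistant", 45.0, n=4),
    ]
}


def get_scenario(name: str, **overrides) -> Scenario:
    """Look up a built-in scenario, optionally overriding its parameters."""
    try:
        s = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        ) from None
    return replace(s, **overrides) if overrides else s


def _truncated_normal(
    mu: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    if sigma == 0:
        return mu.copy()
    a = (0.0 - mu) / sigma
    b = (1.0 - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng)


def generate_scenario(
    s: Union[Scenario, str],
    seed: int,
    order: Optional[DispensationOrder] = None,
) -> ReplicateSet:
    """Simulate and quantify all replicates of a scenario.

    Each replicate: draw true fractions ~ truncated Gaussian(mean, sd),
    simulate a pyrogram under the scenario's noise CV, quantify it.  The
    dispensation order defaults to a generated fully identifiable order
    for the scenario's template.  Deterministic for a fixed seed.
    """
    if isinstance(s, str):
        s = get_scenario(s)
    seq = DegenerateSequence(bases=s.template, source_id=s.name)
    if len(seq.cpg_positions) != len(s.per_site_means):
        raise ValueError(
            f"scenario {s.name!r}: {len(s.per_site_means)} means for a template "
            f"with {len(seq.cpg_positions)} CpG sites"
        )
    if order is None:
        order = generate_dispensation(seq)
    rng = np.random.default_rng(seed)
    mu = np.asarray(s.per_site_means, dtype=float) / 100.0
    calls = []
    for _ in range(s.n):
        truth = _truncated_normal(mu, s.sd / 100.0, rng)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        p = simulate_pyrogram(seq, truth, order, noise_cv=s.noise_cv, seed=rep_seed)
        calls.append(quantify(p, seq))
    return ReplicateSet(condition=s.name, replicates=tuple(calls))
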