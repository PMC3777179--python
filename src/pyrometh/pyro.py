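"""Pyrogram simulation and per-CpG methylation quantification.

The forward model: dispensing base b makes every molecule class whose next
template base matches b extend through the maximal matching run, and the
detected luminescence is proportional to the number of bases incorporated
(linear, unsaturated — homopolymer nonlinearity only matters for runs far
longer than these assays contain).  Peak heights are in arbitrary units;
only ratios are meaningful, so quantification fits a common scale.

Observed heights carry multiplicative Gaussian noise with a configurable
coefficient of variation, truncated at zero.

Quantification inverts the model by least squares in the per-site
methylation variables plus the scale.  For orders that keep the molecule
mixture in phase (see :mod:`pyrometh.dispense`) the expected signal is
exactly linear and the fit reduces, when each site's C and T peaks are
isolated, to the classic per-site ratio m% = 100 * h_C / (h_C + h_T).  For
out-of-phase orders (e.g. vendor-printed ones) the exact multilinear model
is refined by bounded nonlinear least squares from the linear solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dispense import (
    CONVERSION,
    DesignMatrix,
    DispensationOrder,
    design_matrix,
    expected_heights,
)
from .seqcore import DegenerateSequence

#: Conversion-control pass threshold: control peak at most this fraction of
#: the mean single-base reference peak.
CONVERSION_THRESHOLD = 0.05
#: Per-site relative-residual thresholds for quality colors.
QUALITY_BLUE = 0.05
QUALITY_YELLOW = 0.15

PASS, FAIL, NOT_APPLICABLE = "pass", "fail", "not_applicable"


class UnidentifiableSiteError(ValueError):
    """The design matrix is rank-deficient; some sites cannot be resolved."""

    def __init__(self, sites: Sequence[int]):
        self.sites = tuple(sites)
        super().__init__(
            f"dispensation order cannot resolve CpG site(s) {list(self.sites)}: "
            "expected-signal design matrix is rank-deficient"
        )


@dataclass(frozen=True)
class Pyrogram:
    """Peak heights per dispensation, with the order that produced them.

    ``enzyme_mark`` and ``substrate_mark`` record the E/S annotations that
    precede the dispensations on an instrument trace; they carry no signal
    and exist so round-tripped reports can reproduce the anatomy of a run.
    """

    order: DispensationOrder
    heights: np.ndarray
    enzyme_mark: bool = True
    substrate_mark: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.shape != (len(self.order),):
            raise ValueError(
                f"heights length {h.shape} does not match order length {len(self.order)}"
            )
        if np.any(h < 0):
            raise ValueError("peak heights must be non-negative")
        object.__setattr__(self, "heights", h)


@dataclass(frozen=True)
class FitResult:
    """Diagnostics from a quantification fit."""

    scale: float
    fractions: np.ndarray  # per-site methylation in [0, 1]
    fitted: np.ndarray
    residuals: np.ndarray
    design: DesignMatrix


@dataclass(frozen=True)
class MethylationCall:
    """Per-CpG methylation percentages with quality and QC outcomes."""

    per_site_percent: tuple[float, ...]
    per_site_quality: tuple[str, ...]
    conversion_check: str  # pass | fail | not_applicable
    fit: Optional[FitResult] = None

    def __post_init__(self) -> None:
        if not self.per_site_percent:
            raise ValueError("a methylation call needs at least one CpG site")
        if any(not 0.0 <= p <= 100.0 for p in self.per_site_percent):
            raise ValueError("site percentages must lie in [0, 100]")

    @property
    def total_percent(self) -> float:
        """Total (global) methylation: arithmetic mean over CpG sites."""
        return float(np.mean(self.per_site_percent))

    @property
    def n_sites(self) -> int:
        return len(self.per_site_percent)


def simulate_pyrogram(
    seq: DegenerateSequence,
    m: Sequence[float],
    order: Union[DispensationOrder, str],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> Pyrogram:
    """Simulate a pyrogram for per-site methylation fractions ``m``.

    Noiseless heights come from the exact mixture model; the observed
    height is ``noiseless * (1 + N(0, noise_cv))`` truncated at zero, so a
    structurally empty dispensation (blank or conversion control on a
    clean template) stays exactly zero.  Deterministic for a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if isinstance(order, str):
        order = DispensationOrder.from_string(order)
    clean = expected_heights(seq, m, order)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        observed = np.maximum(clean * (1.0 + rng.normal(0.0, noise_cv, clean.size)), 0.0)
    else:
        observed = clean
    return Pyrogram(
        order=order,
        heights=observed,
        meta={"template_id": seq.source_id, "seed": int(seed), "noise_cv": float(noise_cv)},
    )


# --- quantification --------------------------------------------------------

def _linear_fit(dm: DesignMatrix, h: np.ndarray) -> tuple[float, np.ndarray]:
    # h ~ s * intercept + sum_i (s * m_i) * col_i is linear in (s, s*m).
    a = dm.matrix
    beta, *_ = np.linalg.lstsq(a, h, rcond=None)
    s = beta[0]
    if s <= 0:
        # degenerate (e.g. all-zero input); report zero methylation at unit scale
        return max(s, 1e-12), np.zeros(dm.n_sites)
    return float(s), np.clip(beta[1:] / s, 0.0, 1.0)


def quantify(p: Pyrogram, seq: DegenerateSequence, refine: bool = True) -> MethylationCall:
    """Estimate per-CpG methylation from a pyrogram.

    Raises :class:`UnidentifiableSiteError` when the order cannot resolve
    every site.  The fit estimates the common scale jointly with the site
    fractions; estimates are clipped to [0, 100]%.  Quality colors and the
    bisulfite-conversion check are populated from the fit.
    """
    dm = design_matrix(seq, p.order)
    if not dm.full_rank:
        raise UnidentifiableSiteError(dm.unidentifiable_sites() or range(1, dm.n_sites + 1))

    h = p.heights
    s, m = _linear_fit(dm, h)

    if refine and not dm.exact_linear and dm.n_sites:
        x0 = np.concatenate([[s], m])
        lo = np.concatenate([[1e-9], np.zeros(dm.n_sites)])
        hi = np.concatenate([[np.inf], np.ones(dm.n_sites)])
        sol = least_squares(
            lambda x: x[0] * expected_heights(seq, x[1:], p.order) - h,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
        )
        s, m = float(sol.x[0]), sol.x[1:]

    fitted = s * expected_heights(seq, m, p.order)
    fit = FitResult(scale=s, fractions=m, fitted=fitted, residuals=h - fitted, design=dm)
    quality = assign_quality(p, fit)
    conversion = qc_conversion(p, seq).status
    return MethylationCall(
        per_site_percent=tuple(float(x) for x in np.clip(100.0 * m, 0.0, 100.0)),
        per_site_quality=quality,
        conversion_check=conversion,
        fit=fit,
    )


def assign_quality(
    p: Pyrogram,
    fit: FitResult,
    blue: float = QUALITY_BLUE,
    yellow: float = QUALITY_YELLOW,
) -> tuple[str, ...]:
    """Color each CpG site by the relative fit residual at its dispensations.

    The site's relative residual is sum |observed - fitted| over the
    dispensations carrying that site's signal, divided by the fitted signal
    there: at most ``blue`` -> "blue" (good), at most ``yellow`` ->
    "yellow" (pass), otherwise "red" (bad).
    """
    colors = []
    for site in range(1, fit.design.n_sites + 1):
        idx = fit.design.site_dispensations(site)
        denom = float(np.sum(np.abs(fit.fitted[idx])))
        num = float(np.sum(np.abs(fit.residuals[idx])))
        rel = num / denom if denom > 0 else (0.0 if num == 0 else np.inf)
        colors.append("blue" if rel <= blue else "yellow" if rel <= yellow else "red")
    return tuple(colors)


@dataclass(frozen=True)
class ConversionQC:
    status: str  # pass | fail | not_applicable
    ratio: Optional[float] = None  # control height / reference peak


def qc_conversion(
    p: Pyrogram,
    seq: Optional[DegenerateSequence] = None,
    threshold: float = CONVERSION_THRESHOLD,
) -> ConversionQC:
    """Bisulfite-conversion check from the conversion-control dispensation.

    Passes when the control peak is at most ``threshold`` times the
    reference single-base peak height.  With the template available the
    reference is the mean height of dispensations whose expected
    incorporation is exactly one base regardless of methylation; without
    it, the median positive non-control peak is used as an approximation.
    Returns ``not_applicable`` when the order carries no conversion
    control.
    """
    controls = p.order.control_positions(CONVERSION)
    if not controls:
        return ConversionQC(status=NOT_APPLICABLE)

    if seq is not None:
        dm = design_matrix(seq, p.order)
        unit = np.flatnonzero(
            np.isclose(dm.intercept, 1.0)
            & np.all(np.abs(dm.site_columns) < 1e-12, axis=1)
        )
        reference = float(np.mean(p.heights[unit])) if unit.size else float("nan")
    else:
        noncontrol = np.array(
            [h for h, mark in zip(p.heights, p.order.control_marks) if mark == NONE]
        )
        positive = noncontrol[noncontrol > 0]
        reference = float(np.median(positive)) if positive.size else float("nan")

    control_height = float(np.max(p.heights[list(controls)]))
    if not np.isfinite(reference) or reference <= 0:
        return ConversionQC(status=FAIL if control_height > 0 else PASS, ratio=None)
    ratio = control_height / reference
    return ConversionQC(status=PASS if ratio <= threshold else FAIL, ratio=ratio)


# --- peak-table I/O --------------------------------------------------------

PEAK_COLUMNS = ["dispensation_index", "base", "height", "control_flag"]


def write_peak_table(p: Pyrogram, path: Union[str, Path]) -> None:
    """Write a pyrogram as a tab-separated peak table."""
    df = pd.DataFrame(
        {
            "dispensation_index": np.arange(1, len(p.order) + 1),
            "base": list(p.order.bases),
            "height": p.heights,
            "control_flag": list(p.order.control_marks),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_peak_table(path: Union[str, Path]) -> Pyrogram:
    """Read a tab-separated peak table back into a pyrogram."""
    df = pd.read_csv(path, sep="\t", dtype={"base": str, "control_flag": str})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} missing columns: {missing}")
    df = df.sort_values("dispensation_index")
    order = DispensationOrder(
        bases="".join(df["base"]), control_marks=tuple(df["control_flag"])
    )
    return Pyrogram(order=order, heights=df["height"].to_numpy(dtype=float))
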