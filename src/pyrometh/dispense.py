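"""Dispensation orders for degenerate (bisulfite-converted) templates.

In pyrosequencing, nucleotides are dispensed one at a time in a fixed
order; every molecule whose next template base matches the dispensed base
extends through the maximal matching run, and the light emitted is
proportional to the total number of bases incorporated.  Over a converted
template the molecule population is a mixture: at each CpG (Y) a fraction
m of molecules reads C (methylated) and 1-m reads T.  This module provides

* the noiseless signal model (lazy position-merged class tracking, exact
  for arbitrary per-site methylation fractions, plus the brute-force
  2^k-class enumeration used as its oracle),
* the expected-signal design matrix in the per-site methylation variables,
* generation of dispensation orders that keep all branch classes in phase
  (and therefore make every site identifiable), and
* validation of arbitrary, e.g. vendor-supplied, orders.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .seqcore import DegenerateSequence

BLANK = "blank_control"
CONVERSION = "conversion_control"
NONE = "none"

#: Relative singular-value cutoff below which a design is called rank-deficient.
RANK_TOL = 1e-9


@dataclass(frozen=True)
class DispensationOrder:
    """A nucleotide dispensation order with per-position control marks.

    ``blank_control`` marks a deliberately non-incorporating dispensation
    (background / build-reaction control); ``conversion_control`` marks a C
    dispensed where only unconverted cytosine could incorporate, so any
    signal there reveals incomplete bisulfite conversion.
    """

    bases: str
    control_marks: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("dispensation order must be non-empty")
        bad = set(self.bases) - set("ACGT")
        if bad:
            raise ValueError(f"dispensation order contains non-ACGT bases: {sorted(bad)}")
        if self.control_marks is None:
            object.__setattr__(self, "control_marks", (NONE,) * len(self.bases))
        else:
            marks = tuple(self.control_marks)
            if len(marks) != len(self.bases):
                raise ValueError("control_marks length must equal order length")
            bad_marks = set(marks) - {BLANK, CONVERSION, NONE}
            if bad_marks:
                raise ValueError(f"unknown control marks: {sorted(bad_marks)}")
            object.__setattr__(self, "control_marks", marks)

    def __len__(self) -> int:
        return len(self.bases)

    @classmethod
    def from_string(cls, bases: str) -> "DispensationOrder":
        """An order with no control annotations (e.g. a vendor-printed order)."""
        return cls(bases=bases)

    def control_positions(self, kind: str) -> tuple[int, ...]:
        return tuple(i for i, m in enumerate(self.control_marks) if m == kind)


# --- noiseless signal model ------------------------------------------------

def expected_heights(
    seq: DegenerateSequence,
    m: Sequence[float],
    order: Union[DispensationOrder, str],
) -> np.ndarray:
    """Noiseless peak heights for per-site methylation fractions ``m``.

    Tracks the molecule mixture lazily as weight per state.  A state is
    the current template position plus, when that position is a CpG whose
    branch has already been revealed (the molecule sat at the Y through an
    earlier C or T dispensation without incorporating), the revealed base.
    Classes in the same state are statistically indistinguishable and are
    merged, so at most a handful of states are live at any time.  Exact —
    equal to the weighted sum over all 2^k explicit branch classes.
    """
    bases = seq.bases
    order_bases = order.bases if isinstance(order, DispensationOrder) else order
    m = np.asarray(m, dtype=float)
    if m.shape != (len(seq.cpg_positions),):
        raise ValueError(
            f"expected {len(seq.cpg_positions)} methylation fractions, got {m.shape}"
        )
    if np.any((m < 0.0) | (m > 1.0)):
        raise ValueError("methylation fractions must lie in [0, 1]")
    site_at = {p - 1: i for i, p in enumerate(seq.cpg_positions)}

    n = len(bases)
    # state key: (position, revealed branch base at that position or None)
    state: dict[tuple[int, Optional[str]], float] = {(0, None): 1.0}
    heights = np.zeros(len(order_bases))
    for d, b in enumerate(order_bases):
        new: dict[tuple[int, Optional[str]], float] = {}
        h = 0.0
        for (pos, pending), w in state.items():
            while pos < n and w > 0.0:
                sym = bases[pos]
                if sym == b:
                    h += w
                    pos += 1
                elif sym == "Y":
                    if pending is not None:
                        if b == pending:
                            h += w
                            pos += 1
                            pending = None
                        else:
                            break
                    elif b in ("C", "T"):
                        mi = m[site_at[pos]]
                        adv = w * (mi if b == "C" else 1.0 - mi)
                        stay = w - adv
                        if stay > 0.0:
                            # non-incorporating molecules are now known to
                            # carry the other base at this CpG
                            other = "T" if b == "C" else "C"
                            key = (pos, other)
                            new[key] = new.get(key, 0.0) + stay
                        h += adv
                        w = adv
                        pos += 1
                    else:
                        break
                else:
                    break
            key = (pos, pending if pos < n and bases[pos] == "Y" else None)
            new[key] = new.get(key, 0.0) + w
        heights[d] = h
        state = new
    return heights


def _simulate_concrete(bases: str, order_bases: str) -> tuple[np.ndarray, int]:
    """Extend a single concrete (Y-free) molecule; return heights and final position."""
    pos, n = 0, len(bases)
    heights = np.zeros(len(order_bases))
    for d, b in enumerate(order_bases):
        while pos < n and bases[pos] == b:
            heights[d] += 1.0
            pos += 1
    return heights, pos


def enumerate_branch_classes(
    seq: DegenerateSequence, order: Union[DispensationOrder, str]
):
    """Brute-force enumeration of all 2^k branch classes.

    Yields ``(branch, heights, final_pos)`` where ``branch`` assigns C
    (methylated) or T (unmethylated) to each CpG in order.  Serves as the
    independent oracle for :func:`expected_heights` and powers
    :func:`validate_dispensation`.
    """
    order_bases = order.bases if isinstance(order, DispensationOrder) else order
    k = len(seq.cpg_positions)
    for branch in itertools.product("CT", repeat=k):
        concrete = list(seq.bases)
        for p, b in zip(seq.cpg_positions, branch):
            concrete[p - 1] = b
        heights, pos = _simulate_concrete("".join(concrete), order_bases)
        yield branch, heights, pos


def brute_force_heights(
    seq: DegenerateSequence, m: Sequence[float], order: Union[DispensationOrder, str]
) -> np.ndarray:
    """Oracle: weighted sum of explicit branch-class pyrograms (O(2^k))."""
    m = np.asarray(m, dtype=float)
    total = None
    for branch, heights, _ in enumerate_branch_classes(seq, order):
        w = 1.0
        for mi, b in zip(m, branch):
            w *= mi if b == "C" else 1.0 - mi
        total = w * heights if total is None else total + w * heights
    return total


# --- design matrix ---------------------------------------------------------

_design_cache: dict[tuple[str, str], "DesignMatrix"] = {}


@dataclass(frozen=True)
class DesignMatrix:
    """Expected-signal model h(m) ~ intercept + sum_i site_columns[:, i] * m_i.

    ``intercept`` is the fully unmethylated signal h(0); column i is
    h(e_i) - h(0).  For orders that keep all branch classes in phase the
    model is exactly linear in m; otherwise it is the linearization at
    m = 0 of the exact multilinear signal, and ``exact_linear`` is False.
    """

    intercept: np.ndarray
    site_columns: np.ndarray  # (n_dispensations, k)
    singular_values: np.ndarray
    exact_linear: bool

    @property
    def n_sites(self) -> int:
        return self.site_columns.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """Columns [intercept | site columns], the matrix whose rank decides identifiability."""
        return np.column_stack([self.intercept, self.site_columns])

    @property
    def rank(self) -> int:
        s = self.singular_values
        if not s.size or s[0] == 0.0:
            return 0
        return int(np.sum(s > RANK_TOL * s[0]))

    @property
    def full_rank(self) -> bool:
        return self.rank == self.matrix.shape[1]

    def unidentifiable_sites(self) -> tuple[int, ...]:
        """1-based indices of CpG sites involved in the design's null space."""
        if self.full_rank:
            return ()
        a = self.matrix
        _, s, vt = np.linalg.svd(a, full_matrices=True)
        cutoff = RANK_TOL * (s[0] if s.size and s[0] > 0 else 1.0)
        rank = int(np.sum(s > cutoff))
        null = vt[rank:]
        sites = set()
        for vec in null:
            for i, coef in enumerate(vec[1:]):  # skip intercept coefficient
                if abs(coef) > RANK_TOL:
                    sites.add(i + 1)
        return tuple(sorted(sites))

    def site_dispensations(self, site: int) -> np.ndarray:
        """Indices of dispensations carrying signal from 1-based ``site``."""
        return np.flatnonzero(np.abs(self.site_columns[:, site - 1]) > 1e-12)


def design_matrix(
    seq: DegenerateSequence, order: Union[DispensationOrder, str]
) -> DesignMatrix:
    """Build (and cache) the expected-signal design for a template/order pair."""
    order_bases = order.bases if isinstance(order, DispensationOrder) else order
    key = (seq.bases, order_bases)
    cached = _design_cache.get(key)
    if cached is not None:
        return cached

    k = len(seq.cpg_positions)
    h0 = expected_heights(seq, np.zeros(k), order_bases)
    cols = np.empty((len(order_bases), k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = 1.0
        cols[:, i] = expected_heights(seq, e, order_bases) - h0
    a = np.column_stack([h0, cols])
    s = np.linalg.svd(a, compute_uv=False)

    if k:
        mid = np.full(k, 0.5)
        exact = bool(
            np.allclose(
                expected_heights(seq, mid, order_bases), h0 + cols @ mid, atol=1e-12
            )
        )
    else:
        exact = True
    dm = DesignMatrix(
        intercept=h0, site_columns=cols, singular_values=s, exact_linear=exact
    )
    _design_cache[key] = dm
    return dm


# --- order generation ------------------------------------------------------

def _expanded_window(seq: DegenerateSequence, width: int) -> set[str]:
    syms = set()
    for b in seq.bases[:width]:
        syms.update("CT" if b == "Y" else b)
    return syms


def generate_dispensation(
    seq: DegenerateSequence, include_controls: bool = True
) -> DispensationOrder:
    """Derive a dispensation order that resolves every CpG in phase.

    Walking the template 5'->3': a homopolymer run is served by a single
    dispensation of its base; at each Y a C dispensation (methylated
    branch) and then a T dispensation (unmethylated branch) are emitted, so
    every molecule class has passed the site before the walk advances.
    This keeps the mixture in phase throughout, which makes the expected
    signal exactly linear in the per-site fractions and every site
    identifiable.

    With ``include_controls`` the order is prefixed by a blank dispensation
    (a base no molecule can incorporate at the template start, preferring
    one absent from the early template window) and a bisulfite-conversion
    control C.  Controls are omitted with a warning when the template
    starts with C or Y (a leading C dispensation would then carry signal).
    """
    bases = seq.bases
    body: list[str] = []
    pos = 0
    while pos < len(bases):
        b = bases[pos]
        if b == "Y":
            body += ["C", "T"]
            pos += 1
        else:
            body.append(b)
            while pos < len(bases) and bases[pos] == b:
                pos += 1
    marks = [NONE] * len(body)

    if include_controls:
        first = set("CT" if bases[0] == "Y" else bases[0])
        candidates = [b for b in "GACT" if b not in first]
        if not candidates:  # unreachable with a 4-letter alphabet; kept for safety
            warnings.warn("no blank base exists for this template; controls omitted")
            return DispensationOrder(bases="".join(body), control_marks=tuple(marks))
        window = _expanded_window(seq, 10)
        preferred = [b for b in candidates if b not in window]
        blank = (preferred or candidates)[0]
        prefix, prefix_marks = [blank], [BLANK]
        if bases[0] in ("C", "Y"):
            warnings.warn(
                "template starts with C/Y: conversion-control dispensation omitted"
            )
        else:
            prefix.append("C")
            prefix_marks.append(CONVERSION)
        body = prefix + body
        marks = prefix_marks + marks
    return DispensationOrder(bases="".join(body), control_marks=tuple(marks))


# --- order validation ------------------------------------------------------

@dataclass(frozen=True)
class CoverageReport:
    """How completely and identifiably an order reads a template."""

    template: str
    order: str
    class_fractions: dict  # branch tuple -> fraction of template consumed
    complete: bool  # every branch class extends to the template end
    design: DesignMatrix

    @property
    def full_rank(self) -> bool:
        return self.design.full_rank

    @property
    def identifiable(self) -> bool:
        return self.full_rank

    @property
    def unidentifiable_sites(self) -> tuple[int, ...]:
        return self.design.unidentifiable_sites()

    def as_dict(self) -> dict:
        return {
            "template": self.template,
            "order": self.order,
            "complete": self.complete,
            "identifiable": self.identifiable,
            "unidentifiable_sites": list(self.unidentifiable_sites),
            "class_fractions": {
                "".join(k): v for k, v in self.class_fractions.items()
            },
        }


def validate_dispensation(
    seq: DegenerateSequence, order: Union[DispensationOrder, str]
) -> CoverageReport:
    """Simulate all 2^k branch classes under ``order`` and report coverage.

    Problems are reported, never raised: the report states the fraction of
    template each class consumes, whether all classes finish, and whether
    the expected-signal design has full column rank (all sites jointly
    identifiable along with the common scale).
    """
    n = len(seq.bases)
    fractions = {}
    complete = True
    for branch, _, pos in enumerate_branch_classes(seq, order):
        fractions[branch] = pos / n
        complete = complete and pos == n
    return CoverageReport(
        template=seq.bases,
        order=order.bases if isinstance(order, DispensationOrder) else order,
        class_fractions=fractions,
        complete=complete,
        design=design_matrix(seq, order),
    )
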