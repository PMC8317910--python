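"""Relational logit life-table system.

The one-parameter (Brass) relational model expresses any life table through a
standard ``l_s(x)`` via

    logit{l(x)} = alpha + beta * logit{l_s(x)},      logit(l) = 0.5*ln((1-l)/l)

with ``beta`` fixed at 1, so a single level parameter ``alpha`` indexes the
whole family.  ``alpha = 0`` reproduces the standard itself; positive alpha
means heavier mortality.  This module provides the logit transform, the
``q(x) <-> alpha`` conversions used by the indirect child-mortality method, and
a loader for standard life tables shipped as CSV package data.

Shipped standards
-----------------
``west_pattern_synthetic``
    A synthetic standard that follows the Coale-Demeny *West* family's child
    mortality age shape (high infant share of under-five deaths).  It is
    constructed, not transcribed from the printed West tables, and is labelled
    accordingly; because alpha absorbs level shifts, estimates are insensitive
    to the particular reasonable standard used, but the choice is recorded in
    all output metadata.
``unit_test_exp``
    Closed-form ``l_s(x) = exp(-0.03 x)``; used by the test-suite so that
    correctness of the code never hinges on any transcription.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "RelationalLogitStandard",
    "logit_survivorship",
    "alpha_from_q",
    "q5_from_alpha",
    "survivorship_from_alpha",
    "load_standard",
    "available_standards",
    "exponential_standard",
]

#: ages every standard must cover (exact childhood ages used by the indirect method)
REQUIRED_AGES = (1, 2, 3, 5, 10, 15, 20)

# name -> (csv filename, sha256 of file contents); guards against silent edits
# of the shipped reference data.
_REGISTRY: dict[str, tuple[str, str]] = {
    "west_pattern_synthetic": (
        "west_pattern_synthetic.csv",
        "60e029d4af01ffa6b785c1407deb5974897ddf050130d71f48e1a62faa2448de",
    ),
}


@dataclass(frozen=True)
class RelationalLogitStandard:
    """A standard life table and its logits.

    Parameters
    ----------
    name : str
        Identifier recorded in output metadata.
    ages : np.ndarray
        Increasing exact ages ``x`` (years); must include 1,2,3,5,10,15,20.
    lx : np.ndarray
        Survivorship ``l_s(x)`` with radix 1, strictly decreasing, in (0, 1).
    meta : dict
        Free-form provenance metadata.
    """

    name: str
    ages: np.ndarray
    lx: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        lx = np.asarray(self.lx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "lx", lx)
        if ages.ndim != 1 or ages.shape != lx.shape:
            raise ValueError("ages and lx must be 1-d arrays of equal length")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("ages must be strictly increasing")
        if not np.all((lx > 0) & (lx < 1)):
            raise ValueError("l_s(x) must lie strictly inside (0, 1); the radix l(0)=1 is excluded")
        if not np.all(np.diff(lx) < 0):
            raise ValueError("l_s(x) must be strictly decreasing in x")
        missing = [a for a in REQUIRED_AGES if a not in ages]
        if missing:
            raise ValueError(f"standard {self.name!r} is missing required ages {missing}")

    def l(self, x: float) -> float:
        """Survivorship ``l_s(x)`` at a tabulated age."""
        idx = np.flatnonzero(self.ages == x)
        if idx.size == 0:
            raise KeyError(f"age {x} not tabulated in standard {self.name!r}")
        return float(self.lx[idx[0]])

    def Y(self, x: float) -> float:
        """Logit ``Y_s(x) = 0.5*ln((1 - l_s(x)) / l_s(x))`` at a tabulated age."""
        return logit_survivorship(self.l(x))

    def q(self, x: float) -> float:
        """Probability of dying by exact age x, ``1 - l_s(x)``."""
        return 1.0 - self.l(x)

    @property
    def logits(self) -> pd.Series:
        return pd.Series([self.Y(a) for a in self.ages], index=self.ages, name="Y_s")


def logit_survivorship(l: float) -> float:
    """Demographers' logit of a survivorship probability.

    ``logit(l) = 0.5 * ln((1 - l) / l)``; note the 0.5 factor and the
    orientation (heavier mortality => larger logit), both conventional in the
    relational life-table literature.
    """
    l = float(l)
    if not 0.0 < l < 1.0:
        raise ValueError(f"logit_survivorship requires 0 < l < 1, got {l}")
    return 0.5 * np.log((1.0 - l) / l)


def alpha_from_q(q_x: float, x: float, standard: RelationalLogitStandard) -> float:
    """Level parameter alpha implied by an observed q(x).

    With beta = 1, ``alpha = 0.5*ln(q/(1-q)) - Y_s(x)``; the first term is the
    logit of the corresponding survivorship ``l(x) = 1 - q(x)``.
    """
    q_x = float(q_x)
    if not 0.0 < q_x < 1.0:
        raise ValueError(f"alpha_from_q requires 0 < q < 1, got {q_x}")
    return 0.5 * np.log(q_x / (1.0 - q_x)) - standard.Y(x)


def survivorship_from_alpha(alpha: float, x: float, standard: RelationalLogitStandard) -> float:
    """``l(x)`` of the relational table at level alpha (beta = 1)."""
    y = alpha + standard.Y(x)
    return 1.0 / (1.0 + np.exp(2.0 * y))


def q5_from_alpha(alpha: float, standard: RelationalLogitStandard) -> float:
    """Under-five death probability 5q0 of the relational table at level alpha.

    ``5q0 = exp(2(alpha + Y_s(5))) / (1 + exp(2(alpha + Y_s(5)))) = 1 - l(5)``.
    """
    y = 2.0 * (float(alpha) + standard.Y(5))
    # logistic form; stable for large |y|
    if y >= 0:
        e = np.exp(-y)
        return float(1.0 / (1.0 + e))
    e = np.exp(y)
    return float(e / (1.0 + e))


def exponential_standard(rate: float = 0.03) -> RelationalLogitStandard:
    """Closed-form synthetic standard ``l_s(x) = exp(-rate*x)`` (unit tests)."""
    ages = np.array(REQUIRED_AGES, dtype=float)
    return RelationalLogitStandard(
        name=f"unit_test_exp_{rate:g}",
        ages=ages,
        lx=np.exp(-rate * ages),
        meta={"kind": "synthetic closed form", "rate": rate},
    )


def _read_standard_csv(name: str, text: str) -> RelationalLogitStandard:
    rows = [
        line for line in text.splitlines() if line.strip() and not line.lstrip().startswith("#")
    ]
    import io

    df = pd.read_csv(io.StringIO("\n".join(rows)))
    return RelationalLogitStandard(
        name=name,
        ages=df["x"].to_numpy(float),
        lx=df["l"].to_numpy(float),
        meta={"kind": "package data"},
    )


def available_standards() -> list[str]:
    return sorted(_REGISTRY) + ["unit_test_exp"]


def load_standard(name: str = "west_pattern_synthetic") -> RelationalLogitStandard:
    """Load a shipped standard life table by name.

    Raises ``KeyError`` listing the available standards for unknown names.
    Loading is pure: loading twice returns equal objects.
    """
    if name == "unit_test_exp":
        return exponential_standard()
    if name not in _REGISTRY:
        raise KeyError(f"unknown standard {name!r}; available: {available_standards()}")
    fname, expected_sha = _REGISTRY[name]
    raw = resources.files("pehsurv.data.standards").joinpath(fname).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha:
        warnings.warn(
            f"standard data file {fname} does not match its recorded checksum; "
            "the shipped reference data may have been edited",
            stacklevel=2,
        )
    std = _read_standard_csv(name, raw.decode())
    std.meta["sha256"] = digest
    return std
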