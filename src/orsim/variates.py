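"""Seeded random-variate generation for operating-room duration modelling.

Durations and delays in the simulator are described by a small set of
distribution families in the moment parameterization commonly used by
commercial OR-simulation tools (Arena-style):

``lognormal_mean_sd(m, s)``
    Lognormal variate whose *arithmetic* mean is ``m`` and arithmetic
    standard deviation is ``s`` (both in minutes).  The underlying
    normal parameters are derived internally; ``m``/``s`` are the
    moments of the returned variate itself.
``shifted_exponential(offset, mean_excess)``
    ``offset + Exponential(mean_excess)``; every draw is >= ``offset``.
``discrete_cdf(p1, v1, p2, v2, ...)``
    Inverse-CDF lookup over alternating (cumulative probability, value)
    pairs, e.g. ``(0.5, 5, 1.0, 15)`` returns 5 or 15 with equal
    probability.
``triangular(lo, mode, hi)``
    Triangular on ``[lo, hi]`` with the given mode.
``fixed(v)``
    Degenerate point mass, useful for deterministic oracle schedules.

The module also provides :class:`RandomStreams`, the reproducible
substream factory that the paired-comparison engine uses to give both
treatment arms *identical* draws (common random numbers).
"""

from __future__ import annotations

import math
import re
import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfigurationError",
    "DistributionSpec",
    "RandomStreams",
    "lognormal_underlying",
    "scaled_sd",
]

KINDS = (
    "lognormal_mean_sd",
    "shifted_exponential",
    "discrete_cdf",
    "triangular",
    "fixed",
)

_NPARAMS = {
    "lognormal_mean_sd": 2,
    "shifted_exponential": 2,
    "triangular": 3,
    "fixed": 1,
}


class ConfigurationError(ValueError):
    """A distribution, policy or run parameter is invalid."""


def lognormal_underlying(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a lognormal with arithmetic
    ``mean`` and ``sd``.

    sigma^2 = ln(1 + (sd/mean)^2),  mu = ln(mean) - sigma^2 / 2.
    """
    if mean <= 0:
        raise ConfigurationError(f"lognormal mean must be > 0, got {mean}")
    if sd < 0:
        raise ConfigurationError(f"lognormal sd must be >= 0, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def scaled_sd(new_mean: float, reference_mean: float, reference_sd: float) -> float:
    """Standard deviation implied by a fixed variability ratio.

    When a distribution's point estimate (mean) is changed, the SD is
    rescaled so the coefficient of variation stays fixed:
    ``new_mean * reference_sd / reference_mean``.
    """
    for name, v in (
        ("new_mean", new_mean),
        ("reference_mean", reference_mean),
        ("reference_sd", reference_sd),
    ):
        if v <= 0:
            raise ConfigurationError(f"scaled_sd requires {name} > 0, got {v}")
    return new_mean * (reference_sd / reference_mean)


_ARENA_RE = re.compile(
    r"""^\s*
        (?:(?P<offset>[0-9.]+)\s*\+\s*)?         # optional '10+' shift
        (?P<name>[A-Za-z]+)\s*
        [({\s]\s*(?P<args>[-0-9.,\s]+?)\s*[)}]?\s*$
    """,
    re.VERBOSE,
)

_ARENA_NAMES = {
    "LOGN": "lognormal_mean_sd",
    "EXPO": "shifted_exponential",
    "DISC": "discrete_cdf",
    "TRIA": "triangular",
    "CONST": "fixed",
    "FIXED": "fixed",
}


@dataclass(frozen=True)
class DistributionSpec:
    """A duration/delay distribution in moment parameterization.

    Parameters are validated on construction; invalid values raise
    :class:`ConfigurationError` naming the offending parameter.
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.kind not in KINDS:
            raise ConfigurationError(
                f"unknown distribution kind {self.kind!r}; expected one of {KINDS}"
            )
        p = self.params
        want = _NPARAMS.get(self.kind)
        if want is not None and len(p) != want:
            raise ConfigurationError(
                f"{self.kind} takes {want} parameters, got {len(p)}: {p}"
            )
        if self.kind == "lognormal_mean_sd":
            lognormal_underlying(*p)  # validates
        elif self.kind == "shifted_exponential":
            offset, excess = p
            if offset < 0:
                raise ConfigurationError(f"shifted_exponential offset must be >= 0, got {offset}")
            if excess <= 0:
                raise ConfigurationError(
                    f"shifted_exponential mean-of-excess must be > 0, got {excess}"
                )
        elif self.kind == "triangular":
            lo, mode, hi = p
            if not (lo <= mode <= hi):
                raise ConfigurationError(f"triangular requires min <= mode <= max, got {p}")
            if lo <= 0:
                raise ConfigurationError(f"triangular min must be > 0, got {lo}")
        elif self.kind == "fixed":
            if p[0] <= 0:
                raise ConfigurationError(f"fixed value must be > 0, got {p[0]}")
        elif self.kind == "discrete_cdf":
            if len(p) < 2 or len(p) % 2:
                raise ConfigurationError(
                    f"discrete_cdf takes alternating (cum. probability, value) pairs, got {p}"
                )
            probs, values = p[0::2], p[1::2]
            if any(b <= a for a, b in zip(probs, probs[1:])):
                raise ConfigurationError(
                    f"discrete_cdf cumulative probabilities must strictly increase, got {probs}"
                )
            if probs[0] <= 0 or abs(probs[-1] - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"discrete_cdf cumulative probabilities must end at 1, got {probs}"
                )
            if any(v <= 0 for v in values):
                raise ConfigurationError(f"discrete_cdf values must be > 0, got {values}")

    # -- analytic moments -------------------------------------------------

    def mean(self) -> float:
        p = self.params
        if self.kind == "lognormal_mean_sd":
            return p[0]
        if self.kind == "shifted_exponential":
            return p[0] + p[1]
        if self.kind == "discrete_cdf":
            probs = np.diff(np.concatenate([[0.0], np.asarray(p[0::2])]))
            return float(np.dot(probs, p[1::2]))
        if self.kind == "triangular":
            return sum(p) / 3.0
        return p[0]

    def sd(self) -> float:
        p = self.params
        if self.kind == "lognormal_mean_sd":
            return p[1]
        if self.kind == "shifted_exponential":
            return p[1]
        if self.kind == "discrete_cdf":
            probs = np.diff(np.concatenate([[0.0], np.asarray(p[0::2])]))
            values = np.asarray(p[1::2])
            m = float(np.dot(probs, values))
            return math.sqrt(float(np.dot(probs, (values - m) ** 2)))
        if self.kind == "triangular":
            a, b, c = p
            return math.sqrt((a * a + b * b + c * c - a * b - a * c - b * c) / 18.0)
        return 0.0

    # -- sampling ---------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw one variate (``size=None``) or an array of ``size`` variates."""
        p = self.params
        if self.kind == "lognormal_mean_sd":
            if p[1] == 0.0:
                return p[0] if size is None else np.full(size, p[0])
            mu, sigma = lognormal_underlying(*p)
            out = rng.lognormal(mu, sigma, size)
        elif self.kind == "shifted_exponential":
            out = p[0] + rng.exponential(p[1], size)
        elif self.kind == "discrete_cdf":
            cum = np.asarray(p[0::2])
            values = np.asarray(p[1::2])
            u = rng.random(size)
            out = values[np.searchsorted(cum, u, side="right")]
        elif self.kind == "triangular":
            out = rng.triangular(p[0], p[1], p[2], size)
        else:  # fixed
            return p[0] if size is None else np.full(size, p[0])
        return float(out) if size is None else out

    # -- rescaling & parsing ----------------------------------------------

    def with_mean(self, new_mean: float) -> "DistributionSpec":
        """Same family re-centred at ``new_mean``, SD held at a fixed
        variability ratio (all scale parameters multiplied by
        ``new_mean / mean``)."""
        if new_mean <= 0:
            raise ConfigurationError(f"new mean must be > 0, got {new_mean}")
        if self.kind == "lognormal_mean_sd":
            return DistributionSpec(
                self.kind, (new_mean, scaled_sd(new_mean, self.params[0], self.params[1]))
            )
        factor = new_mean / self.mean()
        if self.kind == "discrete_cdf":
            params = list(self.params)
            params[1::2] = [v * factor for v in params[1::2]]
            return DistributionSpec(self.kind, tuple(params))
        return DistributionSpec(self.kind, tuple(v * factor for v in self.params))

    @classmethod
    def from_arena(cls, text: str) -> "DistributionSpec":
        """Parse an Arena-dialect expression such as ``LOGN(72.9,29.2)``,
        ``10+EXPO{25.6}``, ``DISC{0.5,5,1,15}`` or ``TRIA{7.5,15,22.5}``."""
        m = _ARENA_RE.match(text)
        if not m:
            raise ConfigurationError(f"cannot parse arena distribution expression {text!r}")
        name = m.group("name").upper()
        if name not in _ARENA_NAMES:
            raise ConfigurationError(f"unknown arena distribution name {name!r} in {text!r}")
        args = [float(a) for a in re.split(r"[,\s]+", m.group("args").strip()) if a]
        offset = float(m.group("offset")) if m.group("offset") else 0.0
        kind = _ARENA_NAMES[name]
        if kind == "shifted_exponential":
            if len(args) != 1:
                raise ConfigurationError(f"EXPO takes one argument, got {args} in {text!r}")
            return cls(kind, (offset, args[0]))
        if offset:
            raise ConfigurationError(f"'+' shift only supported for EXPO, got {text!r}")
        return cls(kind, tuple(args))


@dataclass(frozen=True)
class RandomStreams:
    """Named, reproducible random substreams derived from one master seed.

    ``rng(purpose, *indices)`` returns an independent generator keyed by
    the purpose label plus any integer indices (replication, day, ...).
    The same ``(master_seed, purpose, indices)`` always reproduces the
    same sequence, and distinct keys give statistically independent
    streams — the backbone of the common-random-numbers paired design,
    where both treatment arms consume draws addressed by the same keys.
    """

    master_seed: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.master_seed) < 2**63):
            raise ConfigurationError(
                f"master_seed must be a non-negative integer < 2**63, got {self.master_seed}"
            )
        object.__setattr__(self, "master_seed", int(self.master_seed))

    def rng(self, purpose: str, *indices: int) -> np.random.Generator:
        key = zlib.crc32(purpose.encode("utf-8"))
        entropy = [self.master_seed, key, *(int(i) for i in indices)]
        return np.random.default_rng(np.random.SeedSequence(entropy))
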