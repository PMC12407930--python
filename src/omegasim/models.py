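"""Nucleotide substitution models and per-base substitution sampling.

Implements the five classical relative-rate models — Jukes-Cantor (JC69),
Kimura 2-parameter (K2P), Kimura 3-parameter (K3P), Felsenstein (F81) and
Hasegawa-Kishino-Yano (HKY85) — as 4x4 rate matrices over the bases in
(T, C, A, G) order, row = existing base, column = mutated base.

Rates are *relative*: every consumer normalizes them per originating base
(only the three off-diagonal entries of a row matter), so no global scaling
to one expected substitution per unit time is performed.  Diagonal entries
are stored as the negative row sum for display only and are never read by
any operation.

Parameter defaults are chosen so that an unconfigured model of any name
collapses to JC69-equivalent behaviour: mu = alpha = beta = kappa = 1,
gamma = beta, pi = uniform.  Unset parameters therefore never silently
bias a simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidBaseError, ParameterError, UnsupportedModelError

#: Canonical base ordering (rows/columns of every rate matrix).
BASES: tuple[str, ...] = ("T", "C", "A", "G")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

MODEL_NAMES: tuple[str, ...] = ("JC69", "K2P", "K3P", "F81", "HKY85")

# K3P transversion classes (standard K3ST convention): beta for the
# A<->T / C<->G exchanges, gamma for A<->C / G<->T.
_K3P_BETA_PAIRS = (frozenset("AT"), frozenset("CG"))


def is_transition(a: str, b: str) -> bool:
    """True when a<->b is purine<->purine or pyrimidine<->pyrimidine."""
    pair = {a, b}
    return pair <= PURINES or pair <= PYRIMIDINES


@dataclass(frozen=True)
class ModelParameters:
    """Relative-rate parameters; only those relevant to a model are consulted.

    alpha  -- transition rate (K2P, K3P)
    beta   -- transversion rate (K2P); A<->T / C<->G transversion rate (K3P)
    gamma  -- A<->C / G<->T transversion rate (K3P); defaults to beta
    kappa  -- transition/transversion ratio (HKY85)
    mu     -- uniform rate (JC69)
    pi     -- equilibrium base frequencies over (T, C, A, G) (F81, HKY85)
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float | None = None
    kappa: float = 1.0
    mu: float = 1.0
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "kappa", "mu"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"parameter '{name}' must be a positive number, got {v!r}")
        if self.gamma is not None and not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ParameterError(f"parameter 'gamma' must be a positive number, got {self.gamma!r}")
        pi = tuple(float(x) for x in self.pi)
        if len(pi) != 4:
            raise ParameterError("parameter 'pi' must have exactly 4 entries (T, C, A, G)")
        if any(x < 0 for x in pi):
            raise ParameterError("parameter 'pi' entries must be non-negative")
        if abs(sum(pi) - 1.0) > 1e-9:
            raise ParameterError(f"parameter 'pi' must sum to 1 (got {sum(pi)!r})")
        object.__setattr__(self, "pi", pi)

    @property
    def gamma_effective(self) -> float:
        return self.beta if self.gamma is None else self.gamma


@dataclass(eq=False)
class SubstitutionModel:
    """A named relative-rate matrix plus its parameters.

    ``rates[i, j]`` is the relative rate of base BASES[i] mutating to
    BASES[j]; the diagonal holds the negative row sum for display only.
    """

    name: str
    rates: np.ndarray
    params: ModelParameters
    _alts: dict[str, tuple[str, ...]] = field(init=False, repr=False)
    _probs: dict[str, dict[str, float]] = field(init=False, repr=False)
    _cum: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        off = self.rates[~np.eye(4, dtype=bool)]
        if not np.all(off > 0):
            raise ParameterError(f"model {self.name}: all off-diagonal rates must be strictly positive")
        self._alts = {b: tuple(a for a in BASES if a != b) for b in BASES}
        self._probs = {}
        self._cum = {}
        for b in BASES:
            i = BASE_INDEX[b]
            raw = np.array([self.rates[i, BASE_INDEX[a]] for a in self._alts[b]], dtype=float)
            p = raw / raw.sum()
            self._probs[b] = {a: float(x) for a, x in zip(self._alts[b], p)}
            self._cum[b] = np.cumsum(p)

    def alternatives(self, from_base: str) -> tuple[str, ...]:
        """The three possible target bases, in canonical (T, C, A, G) order."""
        _check_base(from_base)
        return self._alts[from_base]

    def probabilities(self, from_base: str) -> dict[str, float]:
        _check_base(from_base)
        return dict(self._probs[from_base])

    def rate(self, from_base: str, to_base: str) -> float:
        _check_base(from_base)
        _check_base(to_base)
        if from_base == to_base:
            raise ParameterError("rate() is defined for off-diagonal entries only")
        return float(self.rates[BASE_INDEX[from_base], BASE_INDEX[to_base]])


def _check_base(base: str) -> None:
    if base not in BASE_INDEX:
        raise InvalidBaseError(f"invalid base {base!r}; expected one of T, C, A, G")


def _relative_rate(name: str, a: str, b: str, p: ModelParameters) -> float:
    """Off-diagonal rate a -> b under the named model."""
    if name == "JC69":
        return p.mu
    if name == "K2P":
        return p.alpha if is_transition(a, b) else p.beta
    if name == "K3P":
        if is_transition(a, b):
            return p.alpha
        return p.beta if frozenset((a, b)) in _K3P_BETA_PAIRS else p.gamma_effective
    if name == "F81":
        return p.pi[BASE_INDEX[b]]
    if name == "HKY85":
        target = p.pi[BASE_INDEX[b]]
        return p.kappa * target if is_transition(a, b) else target
    raise UnsupportedModelError(f"unsupported model name {name!r}; expected one of {', '.join(MODEL_NAMES)}")


def build_model(name: str, params: ModelParameters | None = None, **kwargs) -> SubstitutionModel:
    """Construct a substitution model by name.

    Parameters may be given as a :class:`ModelParameters` or as keyword
    arguments (``alpha=``, ``beta=``, ``gamma=``, ``kappa=``, ``mu=``,
    ``pi=``); unset parameters take their JC69-equivalent defaults.
    """
    if params is None:
        try:
            params = ModelParameters(**kwargs)
        except TypeError as exc:
            raise ParameterError(f"unknown model parameter: {exc}") from None
    elif kwargs:
        raise ParameterError("pass either a ModelParameters object or keyword parameters, not both")
    key = str(name).upper()
    if key not in MODEL_NAMES:
        raise UnsupportedModelError(f"unsupported model name {name!r}; expected one of {', '.join(MODEL_NAMES)}")
    rates = np.zeros((4, 4), dtype=float)
    for i, a in enumerate(BASES):
        for j, b in enumerate(BASES):
            if i != j:
                rates[i, j] = _relative_rate(key, a, b, params)
    np.fill_diagonal(rates, -rates.sum(axis=1))  # display only; never consulted
    return SubstitutionModel(key, rates, params)


def substitution_probabilities(model: SubstitutionModel, from_base: str) -> dict[str, float]:
    """Normalized probabilities over the three alternative bases.

    P(alt) = rate(from -> alt) / sum over alternatives; sums to 1.
    """
    return model.probabilities(from_base)


def sample_substitution(model: SubstitutionModel, from_base: str, rng: np.random.Generator) -> str:
    """Draw one alternative base per the model's normalized probabilities.

    Never returns ``from_base``; deterministic given the generator state.
    """
    _check_base(from_base)
    u = rng.random()
    idx = int(np.searchsorted(model._cum[from_base], u, side="right"))
    return model._alts[from_base][min(idx, 2)]


_CONFIG_FLOAT_KEYS = ("alpha", "beta", "gamma", "kappa", "mu")
_CONFIG_PI_KEYS = ("pi_T", "pi_C", "pi_A", "pi_G")


def load_model_config(path: str | Path) -> tuple[str | None, dict]:
    """Read a plain-text ``key=value`` model config file.

    Recognized keys: ``model``, ``alpha``, ``beta``, ``gamma``, ``kappa``,
    ``mu``, ``pi_T``, ``pi_C``, ``pi_A``, ``pi_G``.  Blank lines and lines
    starting with ``#`` are ignored.  Returns ``(model_name_or_None,
    parameter_kwargs)`` suitable for :func:`build_model`.
    """
    name: str | None = None
    kwargs: dict = {}
    pi_parts: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParameterError(f"config line {lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key == "model":
            name = value
        elif key in _CONFIG_FLOAT_KEYS:
            try:
                kwargs[key] = float(value)
            except ValueError:
                raise ParameterError(f"config line {lineno}: '{key}' must be a number, got {value!r}") from None
        elif key in _CONFIG_PI_KEYS:
            try:
                pi_parts[key] = float(value)
            except ValueError:
                raise ParameterError(f"config line {lineno}: '{key}' must be a number, got {value!r}") from None
        else:
            raise ParameterError(f"config line {lineno}: unknown key {key!r}")
    if pi_parts:
        missing = [k for k in _CONFIG_PI_KEYS if k not in pi_parts]
        if missing:
            raise ParameterError(f"config: incomplete pi vector, missing {', '.join(missing)}")
        kwargs["pi"] = tuple(pi_parts[k] for k in _CONFIG_PI_KEYS)
    return name, kwargs
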