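"""AAFT surrogate signals, surrogate p-values, and the modulation index.

Significance of the coupling statistics is assessed against surrogate
high-frequency signals generated with the amplitude-adjusted Fourier
transform (AAFT): each surrogate preserves the amplitude distribution of
V_high exactly (it is a permutation of the original values) and its power
spectrum approximately, while destroying any dependence on the
low-frequency signal. The full statistic pipeline -- envelope extraction,
model refits, surface comparison -- is recomputed per surrogate.

A reference implementation of the modulation index (phase-binned mean
amplitude compared against uniform via normalized KL divergence) is included
for head-to-head comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sg
from scipy.fft import irfft, next_fast_len, rfft

from . import glm
from .coupling import GridEvaluator
from .decompose import BandDecomposition
from .glm import ConvergenceError, GramCache, floor_positive, irls_gamma
from .splines import PeriodicSplineBasis

__all__ = [
    "aaft_surrogate", "surrogate_p_value", "modulation_index",
    "ModulationIndexResult", "SurrogateEnsemble", "SignificanceEngine",
    "run_significance", "P_FLOOR",
]

#: p-value assigned when no surrogate statistic exceeds the observed one.
P_FLOOR = 0.0005

STATISTIC_KINDS = ("r_pac", "r_aac", "mi", "r_pac_condition")


def _ranks(x: np.ndarray) -> np.ndarray:
    """Rank of each sample (0 = smallest), ties broken by first occurrence."""
    r = np.empty(len(x), dtype=np.intp)
    r[np.argsort(x, kind="stable")] = np.arange(len(x))
    return r


def aaft_surrogate(
    v_high: np.ndarray,
    seed: int | np.random.Generator | None = None,
    *,
    _sorted: np.ndarray | None = None,
    _ranks: np.ndarray | None = None,
) -> np.ndarray:
    """One amplitude-adjusted Fourier transform surrogate.

    The signal is mapped onto a Gaussian sequence preserving its rank order,
    the Gaussian copy is phase-randomized in the Fourier domain (Hermitian
    symmetry kept, so the result is real), and the original values are
    mapped back by rank. The surrogate is therefore an exact permutation of
    the input values whose power spectrum approximates the original.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(v_high, dtype=float)
    n = len(x)
    if n < 16:
        raise ValueError("signal too short for a meaningful surrogate")
    xs = np.sort(x) if _sorted is None else _sorted
    rx = globals()["_ranks"](x) if _ranks is None else _ranks

    gauss = np.sort(rng.standard_normal(n))
    y = gauss[rx]  # gaussianized copy, original temporal ordering

    Y = rfft(y)
    phase = rng.uniform(0.0, 2.0 * np.pi, len(Y))
    phase[0] = 0.0
    if n % 2 == 0:
        phase[-1] = 0.0  # keep the Nyquist bin real
    y2 = irfft(np.abs(Y) * np.exp(1j * phase), n)

    out = np.empty(n)
    out[np.argsort(y2, kind="stable")] = xs
    return out


def surrogate_p_value(observed: float, statistics: np.ndarray) -> float:
    """Proportion of surrogate statistics strictly greater than the observed.

    A proportion of zero is reported as the floor ``P_FLOOR`` (one cannot
    resolve a smaller p-value from a finite surrogate ensemble).
    """
    statistics = np.asarray(statistics, dtype=float)
    if statistics.size == 0:
        raise ValueError("empty surrogate ensemble")
    prop = float(np.mean(statistics > observed))
    return prop if prop > 0.0 else P_FLOOR


@dataclass
class SurrogateEnsemble:
    """Per-surrogate statistic values for one statistic kind."""

    kind: str
    statistics: np.ndarray
    observed: float
    n_failed: int = 0

    @property
    def p_value(self) -> float:
        return surrogate_p_value(self.observed, self.statistics)


@dataclass
class ModulationIndexResult:
    """Modulation index and, when computed, its surrogate p-value."""

    mi: float
    n_bins: int
    p_mi: float | None = None


def modulation_index(a_high, phi_low, n_bins: int = 18) -> ModulationIndexResult:
    """Phase-binned modulation index.

    The mean high-frequency amplitude is computed in ``n_bins`` equal phase
    bins, normalized to a probability vector, and compared against the
    uniform distribution via KL divergence scaled by log(n_bins), giving a
    value in [0, 1] (0 = no phase preference).
    """
    a_high = np.asarray(a_high, dtype=float)
    phi_low = np.asarray(phi_low, dtype=float)
    if len(a_high) != len(phi_low):
        raise ValueError("amplitude and phase series have different lengths")
    if n_bins < 2:
        raise ValueError("need at least two phase bins")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, phi_low, side="left") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=a_high, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.empty(n_bins)
    empty = counts == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty phase bin(s); assigning the global "
            "mean amplitude", RuntimeWarning, stacklevel=2)
        means[empty] = a_high.mean()
    means[~empty] = sums[~empty] / counts[~empty]
    p = means / means.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0.0, p * np.log(p), 0.0)
    kl = np.log(n_bins) + plogp.sum()
    return ModulationIndexResult(mi=float(kl / np.log(n_bins)), n_bins=n_bins)


class SignificanceEngine:
    """Shared machinery for observed statistics and surrogate ensembles.

    Designs, Gram factorizations and the surface grid depend only on
    (phi_low, A_low), which AAFT surrogacy leaves untouched; they are built
    once and reused across all surrogate refits. Only the high-frequency
    signal is permuted; its envelope is re-extracted and the affected models
    refit per surrogate.

    Parameters
    ----------
    decomposition : BandDecomposition
        Phase/amplitude series, already trimmed of edge transients.
    basis : PeriodicSplineBasis
    amplitude_is_signal : bool
        When True, ``v_high`` is itself an amplitude series (e.g. a spike
        train plus noise) and surrogates are used directly as amplitudes
        instead of taking a Hilbert envelope.
    """

    def __init__(
        self,
        decomposition: BandDecomposition,
        basis: PeriodicSplineBasis | None = None,
        n_bins_mi: int = 18,
        amplitude_is_signal: bool = False,
    ):
        self.dec = decomposition
        self.basis = basis or PeriodicSplineBasis()
        self.n_bins_mi = n_bins_mi
        self.amplitude_is_signal = amplitude_is_signal

        self.phi = decomposition.phi_low
        self.alow = decomposition.a_low
        self.y = floor_positive(decomposition.a_high)
        self.vhigh = decomposition.v_high
        self._sorted = np.sort(self.vhigh)
        self._rank = _ranks(self.vhigh)
        self._nfft = next_fast_len(len(self.vhigh))

        self.evaluator = GridEvaluator(self.alow, self.basis)
        self._designs: dict[str, tuple[np.ndarray, GramCache]] = {}

    # -- designs ------------------------------------------------------------

    def _design(self, kind: str) -> tuple[np.ndarray, GramCache]:
        if kind not in self._designs:
            P = self.dec.condition
            if kind == "phi":
                X = glm.design_phi(self.phi, self.basis)
            elif kind == "alow":
                X = glm.design_alow(self.alow)
            elif kind == "joint":
                X = glm.design_joint(self.phi, self.alow, self.basis)
            elif kind == "joint+condition":
                X = glm.design_condition_full(self.phi, self.alow, P, self.basis)
            elif kind == "alow+condition":
                X = glm.design_condition_amp(self.phi, self.alow, P, self.basis)
            else:
                raise ValueError(f"unknown design {kind!r}")
            self._designs[kind] = (X, GramCache(X))
        return self._designs[kind]

    def _beta(self, kind: str, y: np.ndarray) -> np.ndarray:
        X, gram = self._design(kind)
        beta, _, _, _ = irls_gamma(X, y, gram, criterion="beta")
        return beta

    _PAIRS = {
        "r_pac": ("alow", "joint"),
        "r_aac": ("phi", "joint"),
        "r_pac_condition": ("alow+condition", "joint+condition"),
    }

    # -- statistics ---------------------------------------------------------

    def statistic(self, kind: str, y: np.ndarray) -> float:
        """Compute one statistic for an amplitude series ``y``."""
        if kind == "mi":
            return modulation_index(y, self.phi, self.n_bins_mi).mi
        num, den = self._PAIRS[kind]
        d = (self.evaluator.log_surface_ends(num, self._beta(num, y))
             - self.evaluator.log_surface_ends(den, self._beta(den, y)))
        return float(np.max(np.abs(1.0 - np.exp(d))))

    def observed(self, kind: str) -> float:
        return self.statistic(kind, self.y)

    def _surrogate_amplitude(self, rng: np.random.Generator) -> np.ndarray:
        vs = aaft_surrogate(self.vhigh, rng, _sorted=self._sorted, _ranks=self._rank)
        if self.amplitude_is_signal:
            return floor_positive(vs)
        env = np.abs(_sg.hilbert(vs, self._nfft)[:len(vs)])
        return floor_positive(env)

    def run(
        self,
        kinds: tuple[str, ...] | str,
        n_surrogates: int = 1000,
        seed: int | np.random.Generator | None = None,
    ) -> dict[str, SurrogateEnsemble]:
        """Observed statistics and surrogate ensembles for one or more kinds.

        All requested statistics are evaluated on the *same* surrogate
        signals. Surrogates on which a model refit fails to converge are
        dropped with a recorded count.
        """
        if isinstance(kinds, str):
            kinds = (kinds,)
        unknown = set(kinds) - set(STATISTIC_KINDS)
        if unknown:
            raise ValueError(f"unknown statistic kind(s) {sorted(unknown)}")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

        obs = {k: self.observed(k) for k in kinds}
        stats: dict[str, list[float]] = {k: [] for k in kinds}
        n_failed = 0
        for _ in range(n_surrogates):
            ys = self._surrogate_amplitude(rng)
            try:
                vals = {k: self.statistic(k, ys) for k in kinds}
            except (ConvergenceError, ValueError):
                n_failed += 1
                continue
            for k, v in vals.items():
                stats[k].append(v)
        if n_failed:
            warnings.warn(
                f"{n_failed}/{n_surrogates} surrogates dropped "
                "(model refit failed)", RuntimeWarning, stacklevel=2)
        return {
            k: SurrogateEnsemble(k, np.asarray(stats[k]), obs[k], n_failed)
            for k in kinds
        }


def run_significance(
    decomposition: BandDecomposition,
    statistic_kind: str,
    n_surrogates: int = 1000,
    seed: int | np.random.Generator | None = None,
    basis: PeriodicSplineBasis | None = None,
    amplitude_is_signal: bool = False,
) -> tuple[float, float]:
    """Observed statistic and AAFT-surrogate p-value for one statistic.

    ``decomposition`` should already be trimmed of edge transients (see
    :meth:`BandDecomposition.trimmed`). For ``r_pac_condition`` the
    decomposition must carry a binary condition indicator.
    """
    engine = SignificanceEngine(
        decomposition, basis, amplitude_is_signal=amplitude_is_signal)
    ens = engine.run(statistic_kind, n_surrogates, seed)[statistic_kind]
    return ens.observed, ens.p_value
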