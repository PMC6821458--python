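"""Model/Results interface for cross-frequency coupling analysis.

`CFCModel` is built from a raw voltage trace (or an existing band
decomposition, or directly from phase/amplitude series); its :meth:`fit`
estimates the three gamma GLMs -- phase-only, amplitude-only and joint --
and returns a :class:`CFCResults` carrying the fits, the coupling statistics
R_PAC and R_AAC, parametric-bootstrap confidence intervals and
AAFT-surrogate p-values on request, and a text summary.

`ConditionCFCModel` extends the analysis with a binary condition indicator
(e.g. pre/post stimulation) and measures whether the phase-coupling profile
itself differs between conditions (R_PAC,condition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import filters
from .coupling import (ConditionResult, CouplingResult, GridEvaluator,
                       SurfaceGrid, bootstrap_r_draws, compute_r_condition)
from .decompose import BandDecomposition, decompose
from .glm import (GammaGLMFit, fit_alow_model, fit_condition_models,
                  fit_joint_model, fit_phi_model)
from .splines import PeriodicSplineBasis
from .surrogates import (ModulationIndexResult, SignificanceEngine,
                         modulation_index)

__all__ = ["AnalysisConfig", "CFCModel", "CFCResults",
           "ConditionCFCModel", "ConditionCFCResults"]

#: Seconds discarded at each record edge before fitting (filter and Hilbert
#: transients).
EDGE_TRIM_S = 1.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved analysis options, echoed into every serialized report."""

    low_band: tuple[float, float] = filters.LOW_BAND
    high_band: tuple[float, float] = filters.HIGH_BAND
    low_order: int = filters.LOW_ORDER
    high_order: int = filters.HIGH_ORDER
    n_splines: int = 10
    tension: float = 0.5
    n_alow_grid: int = 640
    n_phi_grid: int = 100
    alow_quantiles: tuple[float, float] = (0.05, 0.95)
    n_surrogates: int = 1000
    n_bootstrap: int = 10_000
    edge_trim_s: float = EDGE_TRIM_S
    mi_bins: int = 18

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


class _BaseCFCModel:
    """Shared construction: trace -> trimmed decomposition + spline basis."""

    def __init__(self, signal=None, fs=None, *, decomposition=None,
                 condition=None, config: AnalysisConfig | None = None,
                 amplitude_is_signal: bool = False, trim: bool = True):
        self.config = config or AnalysisConfig()
        cfg = self.config
        if decomposition is None:
            if signal is None or fs is None:
                raise ValueError("provide either (signal, fs) or a decomposition")
            decomposition = decompose(
                signal, fs, cfg.low_band, cfg.high_band,
                cfg.low_order, cfg.high_order)
        if condition is not None:
            condition = np.asarray(condition)
            if len(condition) != len(decomposition):
                raise ValueError("condition indicator length mismatch")
            decomposition.condition = condition
        if trim and cfg.edge_trim_s > 0:
            decomposition = decomposition.trimmed(cfg.edge_trim_s)
        self.decomposition = decomposition
        self.basis = PeriodicSplineBasis(cfg.n_splines, cfg.tension)
        self.amplitude_is_signal = amplitude_is_signal

    def _engine(self) -> SignificanceEngine:
        return SignificanceEngine(
            self.decomposition, self.basis, self.config.mi_bins,
            amplitude_is_signal=self.amplitude_is_signal)


class CFCModel(_BaseCFCModel):
    """Cross-frequency coupling model for a single-channel voltage trace.

    Parameters
    ----------
    signal : array_like
        Voltage samples.
    fs : float
        Sampling rate (Hz).
    config : AnalysisConfig, optional
        Bands, filter orders, spline count, grid sizes, trim length.

    Examples
    --------
    >>> from glmcfc import CFCModel, simulate
    >>> sim = simulate.simulate_pac(i_pac=1.0, seed=7)
    >>> res = CFCModel(sim.v, sim.fs).fit()
    >>> 0 <= res.r_pac  # doctest: +SKIP
    """

    @classmethod
    def from_decomposition(cls, decomposition: BandDecomposition,
                           config: AnalysisConfig | None = None,
                           trim: bool = True) -> "CFCModel":
        return cls(decomposition=decomposition, config=config, trim=trim)

    @classmethod
    def from_phase_amplitude(cls, a_high, phi_low, a_low, fs: float = 1.0,
                             config: AnalysisConfig | None = None) -> "CFCModel":
        """Build directly from amplitude/phase series (no filtering step).

        Used when the high-frequency amplitude is observed directly, e.g.
        the spike-train-plus-noise output of the spiking simulator. The
        amplitude series doubles as the signal that surrogates permute.
        """
        a_high = np.asarray(a_high, dtype=float)
        dec = BandDecomposition(
            v_low=np.zeros_like(a_high), v_high=a_high,
            phi_low=np.asarray(phi_low, dtype=float),
            a_low=np.asarray(a_low, dtype=float),
            a_high=a_high, fs=fs)
        return cls(decomposition=dec, config=config,
                   amplitude_is_signal=True, trim=False)

    def fit(self) -> "CFCResults":
        """Fit the phase, amplitude and joint gamma GLMs."""
        d = self.decomposition
        fits = {
            "phi": fit_phi_model(d.a_high, d.phi_low, self.basis),
            "alow": fit_alow_model(d.a_high, d.a_low),
            "joint": fit_joint_model(d.a_high, d.phi_low, d.a_low, self.basis),
        }
        cfg = self.config
        evaluator = GridEvaluator(d.a_low, self.basis, cfg.n_alow_grid,
                                  cfg.n_phi_grid, cfg.alow_quantiles)
        return CFCResults(self, fits, evaluator)


class CFCResults:
    """Fitted coupling models with the derived statistics.

    Attributes
    ----------
    fits : dict
        ``phi``, ``alow`` and ``joint`` :class:`GammaGLMFit` objects.
    r_pac, r_aac : float
        Maximum absolute fractional distances between fitted surfaces.
    """

    def __init__(self, model: CFCModel, fits: dict[str, GammaGLMFit],
                 evaluator: GridEvaluator):
        self.model = model
        self.fits = fits
        self.evaluator = evaluator
        self._surfaces: SurfaceGrid | None = None
        self.ci_pac: tuple[float, float] | None = None
        self.ci_aac: tuple[float, float] | None = None
        self.p_pac: float | None = None
        self.p_aac: float | None = None
        self._mi: ModulationIndexResult | None = None

    # -- statistics ---------------------------------------------------------

    @property
    def r_pac(self) -> float:
        """Phase contribution to the high-frequency amplitude, net of A_low."""
        return self.evaluator.r_statistic(self.fits["alow"], self.fits["joint"])

    @property
    def r_aac(self) -> float:
        """A_low contribution to the high-frequency amplitude, net of phase."""
        return self.evaluator.r_statistic(self.fits["phi"], self.fits["joint"])

    @property
    def surfaces(self) -> SurfaceGrid:
        """Mean-response surfaces of all three models on the shared grid."""
        if self._surfaces is None:
            ev = self.evaluator
            self._surfaces = SurfaceGrid(
                ev.alow_grid, ev.phi_grid,
                {k: ev.surface(f) for k, f in self.fits.items()})
        return self._surfaces

    def modulation_index(self) -> ModulationIndexResult:
        """Reference phase-binned modulation index on the same series."""
        if self._mi is None:
            from .glm import floor_positive

            d = self.model.decomposition
            self._mi = modulation_index(floor_positive(d.a_high), d.phi_low,
                                        self.model.config.mi_bins)
        return self._mi

    # -- uncertainty --------------------------------------------------------

    def conf_int(self, n_draws: int | None = None,
                 seed=None) -> dict[str, tuple[float, float]]:
        """95% parametric-bootstrap CIs for R_PAC and R_AAC.

        Coefficients are resampled from each fit's normal approximation and
        the statistics recomputed per draw.
        """
        n_draws = n_draws or self.model.config.n_bootstrap
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = {}
        for name, num in (("r_pac", "alow"), ("r_aac", "phi")):
            draws = bootstrap_r_draws(self.fits[num], self.fits["joint"],
                                      self.evaluator, n_draws, rng)
            lo, hi = np.quantile(draws, [0.025, 0.975])
            out[name] = (float(lo), float(hi))
        self.ci_pac, self.ci_aac = out["r_pac"], out["r_aac"]
        return out

    def significance(self, statistics=("r_pac", "r_aac"),
                     n_surrogates: int | None = None,
                     seed=None) -> dict[str, float]:
        """AAFT-surrogate p-values, all statistics on shared surrogates."""
        n_surrogates = n_surrogates or self.model.config.n_surrogates
        ens = self.model._engine().run(tuple(statistics), n_surrogates, seed)
        out = {k: e.p_value for k, e in ens.items()}
        self.p_pac = out.get("r_pac", self.p_pac)
        self.p_aac = out.get("r_aac", self.p_aac)
        if "mi" in out and self._mi is not None:
            self._mi.p_mi = out["mi"]
        return out

    # -- reporting ----------------------------------------------------------

    @property
    def result(self) -> CouplingResult:
        return CouplingResult(self.r_pac, self.r_aac, self.ci_pac,
                              self.ci_aac, self.p_pac, self.p_aac)

    def to_dict(self) -> dict:
        return {
            "r_pac": self.r_pac, "r_aac": self.r_aac,
            "ci_pac": self.ci_pac, "ci_aac": self.ci_aac,
            "p_pac": self.p_pac, "p_aac": self.p_aac,
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "config": self.model.config.to_dict(),
            "n_obs": len(self.model.decomposition),
        }

    def summary(self) -> str:
        lines = ["Cross-frequency coupling (gamma GLM) results",
                 "=" * 45]
        d = self.model.decomposition
        cfg = self.model.config
        lines.append(f"observations: {len(d)}  (fs = {d.fs:g} Hz, "
                     f"{len(d) / d.fs:.1f} s after edge trim)")
        lines.append(f"low band: {cfg.low_band} Hz   high band: {cfg.high_band} Hz")
        lines.append(f"spline control points: {cfg.n_splines} "
                     f"(tension {cfg.tension})")
        lines.append("")
        hdr = f"{'model':<8}{'#coef':>6}{'deviance':>14}{'AIC':>14}{'shape nu':>10}"
        lines.append(hdr)
        for k, f in self.fits.items():
            lines.append(f"{k:<8}{len(f.beta):>6}{f.deviance:>14.2f}"
                         f"{f.aic:>14.2f}{f.nu:>10.3f}")
        lines.append("")
        for name, val, ci, p in (("R_PAC", self.r_pac, self.ci_pac, self.p_pac),
                                 ("R_AAC", self.r_aac, self.ci_aac, self.p_aac)):
            s = f"{name:<7}= {val:.4f}"
            if ci is not None:
                s += f"   95% CI [{ci[0]:.4f}, {ci[1]:.4f}]"
            if p is not None:
                s += f"   p = {p:.4g}"
            lines.append(s)
        return "\n".join(lines)


class ConditionCFCModel(_BaseCFCModel):
    """Coupling analysis with a binary condition covariate.

    Fits the joint model extended with condition interactions (full
    P x (splines, A_low) block, and the P x A_low term alone) and compares
    the two at P = 1; a large distance means the phase-coupling profile
    changes with the condition.
    """

    def __init__(self, signal=None, condition=None, fs=None, *,
                 decomposition=None, config: AnalysisConfig | None = None):
        if condition is None and (decomposition is None
                                  or decomposition.condition is None):
            raise ValueError("a binary condition indicator is required")
        super().__init__(signal, fs, decomposition=decomposition,
                         condition=condition, config=config)

    def fit(self) -> "ConditionCFCResults":
        d = self.decomposition
        fit_full, fit_amp = fit_condition_models(
            d.a_high, d.phi_low, d.a_low, d.condition, self.basis)
        cfg = self.config
        evaluator = GridEvaluator(d.a_low, self.basis, cfg.n_alow_grid,
                                  cfg.n_phi_grid, cfg.alow_quantiles)
        return ConditionCFCResults(self, fit_full, fit_amp, evaluator)


class ConditionCFCResults:
    """Condition-extended fits and the R_PAC,condition statistic."""

    def __init__(self, model: ConditionCFCModel, fit_full: GammaGLMFit,
                 fit_amp: GammaGLMFit, evaluator: GridEvaluator):
        self.model = model
        self.fit_full = fit_full
        self.fit_amp = fit_amp
        self.fits = {"joint+condition": fit_full, "alow+condition": fit_amp}
        self.evaluator = evaluator
        self.p: float | None = None

    @property
    def r_pac_condition(self) -> float:
        """Distance between the two condition models evaluated at P = 1."""
        return self.evaluator.r_statistic(self.fit_amp, self.fit_full)

    def significance(self, n_surrogates: int | None = None,
                     seed=None) -> float:
        """AAFT-surrogate p-value for the condition effect on coupling.

        The high-frequency signal is permuted with the condition labels held
        fixed; both condition models are refit per surrogate.
        """
        n_surrogates = n_surrogates or self.model.config.n_surrogates
        ens = self.model._engine().run(("r_pac_condition",), n_surrogates, seed)
        self.p = ens["r_pac_condition"].p_value
        return self.p

    @property
    def result(self) -> ConditionResult:
        return ConditionResult(self.r_pac_condition, self.p)

    def to_dict(self) -> dict:
        return {
            "r_pac_condition": self.r_pac_condition, "p": self.p,
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "config": self.model.config.to_dict(),
            "n_obs": len(self.model.decomposition),
        }

    def summary(self) -> str:
        lines = ["Condition-covariate coupling results", "=" * 38]
        lines.append(f"coefficients: full model {len(self.fit_full.beta)}, "
                     f"amplitude-only condition model {len(self.fit_amp.beta)}")
        s = f"R_PAC,condition = {self.r_pac_condition:.4f}"
        if self.p is not None:
            s += f"   p = {self.p:.4g}"
        lines.append(s)
        return "\n".join(lines)
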