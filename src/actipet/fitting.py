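"""Constrained least-squares estimation of the multi-exponential model.

Two regimes, mirroring how induced-activity TACs are analysed:

* **fixed half-lives** — the half-lives are pinned to the physical values of
  the expected activation products (¹¹C 20.39 min, ¹⁵O 2.04 min, ¹³N
  9.97 min) and only the non-negative amplitudes Sₖ and the constant K are
  estimated.  With frame-averaged exponential basis columns this is a
  non-negative linear least-squares problem, solved exactly (global
  optimum) by NNLS — no multi-start is needed.

* **free half-lives** — amplitudes *and* half-lives are estimated under
  non-negativity, a notoriously ill-conditioned problem; it is solved by
  bounded nonlinear least squares with a deterministic multi-start grid
  around the physical half-lives, warm-starting amplitudes from the fixed
  solve at each candidate.  Components are returned sorted by descending
  half-life so labelling is deterministic.

The objective is the unweighted sum of squared residuals between observed
and predicted frame means; inverse-variance (Poisson) weighting is
available as an option.  95% confidence intervals come either from the
linearized (Jacobian) covariance or from a seeded parametric bootstrap.

Both regimes are exposed as scikit-learn style estimators taking
``X`` = frame bounds, an ``(n_frames, 2)`` array of [start, end] minutes,
and ``y`` = the per-frame mean rates; module-level functions ``fit_fixed``
and ``fit_free`` wrap them for TAC objects.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .decay_model import frame_basis
from .tac_io import TimeActivityCurve

__all__ = [
    "FitConstraints",
    "FitResult",
    "FixedHalfLifeFitter",
    "FreeHalfLifeFitter",
    "fit_fixed",
    "fit_free",
    "normalize_amplitudes",
    "confidence_intervals",
    "grid_search_oracle",
]

PHYSICAL_HALF_LIVES = (20.39, 2.04, 9.97)  # C11, O15, N13, minutes
PHYSICAL_LABELS = ("C11", "O15", "N13")

#: Amplitude below this (relative to the amplitude scale) counts as zero.
_ZERO_ATOL = 1e-9


@dataclass(frozen=True)
class FitConstraints:
    """Constraint set selecting the fitting regime.

    mode="fixed" pins ``fixed_half_lives`` (exactly ``n_components`` of
    them); mode="free" estimates half-lives above ``half_life_lower_bound``
    minutes.  Amplitudes and K are non-negative in both regimes.
    """

    mode: str = "fixed"
    fixed_half_lives: tuple[float, ...] = PHYSICAL_HALF_LIVES
    n_components: int = 3
    amplitude_lower_bound: float = 0.0
    half_life_lower_bound: float = 0.1
    weighting: str = "none"  # "none" | "poisson"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "free"):
            raise ValueError(f"mode must be 'fixed' or 'free', got {self.mode!r}")
        if self.mode == "fixed" and len(self.fixed_half_lives) != self.n_components:
            raise ValueError(
                f"mode='fixed' needs exactly {self.n_components} half-lives, "
                f"got {len(self.fixed_half_lives)}"
            )
        if self.mode == "free" and not self.half_life_lower_bound > 0:
            raise ValueError("half_life_lower_bound must be strictly positive")


@dataclass
class FitResult:
    """Estimated parameters of one TAC fit.

    ``normalized_fractions`` are Sₖ/ΣSₖ (K excluded); None when ΣSₖ = 0.
    ``identified`` flags components whose amplitude is effectively nonzero;
    the half-life of an unidentified component is not meaningful.
    """

    amplitudes: np.ndarray
    half_lives: np.ndarray
    constant: float
    normalized_fractions: Optional[np.ndarray]
    residuals: np.ndarray
    sse: float
    mode: str
    labels: tuple[Optional[str], ...] = ()
    identified: tuple[bool, ...] = ()
    n_starts_used: int = 1
    ci95: dict = field(default_factory=dict)
    ci_reliable: bool = True

    @property
    def fractions_defined(self) -> bool:
        return self.normalized_fractions is not None

    def to_dict(self) -> dict:
        """JSON-ready representation of every field."""
        return {
            "mode": self.mode,
            "amplitudes": [float(s) for s in self.amplitudes],
            "half_lives_min": [float(t) for t in self.half_lives],
            "constant": float(self.constant),
            "normalized_fractions": (
                None
                if self.normalized_fractions is None
                else [float(f) for f in self.normalized_fractions]
            ),
            "labels": list(self.labels),
            "identified": list(self.identified),
            "residuals": [float(r) for r in self.residuals],
            "sse": float(self.sse),
            "n_starts_used": self.n_starts_used,
            "ci95": {
                k: np.asarray(v).tolist() for k, v in self.ci95.items()
            },
            "ci_reliable": self.ci_reliable,
        }


# ---------------------------------------------------------------------------
# input validation shared by both estimators


def _validate_xy(X, y, min_frames: int):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"X must be (n_frames, 2) frame bounds, got {X.shape}")
    if y.shape != (X.shape[0],):
        raise ValueError(f"y must have one rate per frame, got {y.shape}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("frame bounds and rates must be finite")
    if np.any(X[:, 1] <= X[:, 0]):
        raise ValueError("every frame must have end > start")
    if X.shape[0] < min_frames:
        raise ValueError(f"need at least {min_frames} frames, got {X.shape[0]}")
    return X, y


def _weights(y: np.ndarray, weighting: str) -> Optional[np.ndarray]:
    """Per-frame inverse-variance weights, or None for the unweighted fit."""
    if weighting == "none":
        return None
    if weighting == "poisson":
        floor = max(float(np.max(y)) * 1e-3, np.finfo(float).tiny)
        return 1.0 / np.maximum(y, floor)
    raise ValueError(f"unknown weighting {weighting!r}")


def _nnls_amplitudes(
    half_lives: Sequence[float],
    X: np.ndarray,
    y: np.ndarray,
    fit_constant: bool,
    w: Optional[np.ndarray] = None,
):
    """Exact non-negative linear LS solve at fixed half-lives.

    Returns (amplitudes, K, residuals, sse) for the *unweighted* residuals
    (the weighted problem changes the estimate, not the reported residuals).
    """
    A = frame_basis(half_lives, X)
    if fit_constant:
        A = np.column_stack([A, np.ones(len(y))])
    if w is not None:
        sw = np.sqrt(w)
        coef, _ = optimize.nnls(A * sw[:, None], y * sw)
    else:
        coef, _ = optimize.nnls(A, y)
    resid = y - A @ coef
    amps = coef[: len(half_lives)]
    K = float(coef[-1]) if fit_constant else 0.0
    return amps, K, resid, float(resid @ resid)


class _DecayFitterBase(RegressorMixin, BaseEstimator):
    """Shared predict/score and CI machinery for both regimes."""

    def _check_fitted(self):
        if not hasattr(self, "amplitudes_"):
            raise AttributeError("estimator is not fitted; call fit(X, y) first")

    def predict(self, X):
        """Predicted frame-mean rates for frame bounds ``X``."""
        self._check_fitted()
        X = np.asarray(X, dtype=float).reshape(-1, 2)
        return frame_basis(self.half_lives_, X) @ self.amplitudes_ + self.constant_

    @property
    def fractions_(self) -> Optional[np.ndarray]:
        """Normalized count-rate fractions Sₖ/ΣSₖ; None when ΣSₖ = 0."""
        self._check_fitted()
        total = float(np.sum(self.amplitudes_))
        if total <= 0:
            return None
        return self.amplitudes_ / total

    # -- confidence intervals ----------------------------------------------

    def _free_parameter_jacobian(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        raise NotImplementedError

    def _param_value(self, key) -> float:
        kind, idx = key
        if kind == "S":
            return float(self.amplitudes_[idx])
        if kind == "T":
            return float(self.half_lives_[idx])
        return float(self.constant_)

    def _parameter_se(self, X, y) -> dict:
        """Linearized standard error per free parameter, keyed like names."""
        J, names = self._free_parameter_jacobian(X)
        resid = y - self.predict(X)
        dof = max(len(y) - J.shape[1], 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return {key: float(s) for key, s in zip(names, se)}

    def estimate_confidence(
        self, X, y, method: str = "linearized", n_boot: int = 200, seed=None
    ):
        """Attach 95% CIs for the free parameters of the converged fit.

        linearized: covariance ``s² (JᵀJ)⁻¹`` with ``s²`` the residual
        variance, t-based intervals.  bootstrap: parametric resampling from
        the fitted curve with counting-statistics noise — per-frame variance
        proportional to the fitted rate, the proportionality moment-matched
        to the residuals and redrawn per replicate to propagate its own
        uncertainty — then refit and form studentized (bootstrap-t)
        intervals, clipped to the feasible region; reproducible for a fixed
        seed.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float).reshape(-1, 2)
        y = np.asarray(y, dtype=float)
        n = len(y)
        resid = y - self.predict(X)
        n_comp = len(self.amplitudes_)
        amp_ci = np.tile(self.amplitudes_[:, None], (1, 2)).astype(float)
        hl_ci = np.full((n_comp, 2), np.nan)
        k_ci = np.array([self.constant_, self.constant_], dtype=float)
        self.ci_reliable_ = True

        J, names = self._free_parameter_jacobian(X)
        p = J.shape[1]
        dof = max(n - p, 1)
        s2 = float(resid @ resid) / dof

        if method == "linearized":
            JtJ = J.T @ J
            cond = np.linalg.cond(JtJ) if JtJ.size else 0.0
            if not np.isfinite(cond) or cond > 1e12:
                self.ci_reliable_ = False
            cov = s2 * np.linalg.pinv(JtJ)
            half = stats.t.ppf(0.975, dof) * np.sqrt(np.maximum(np.diag(cov), 0.0))
            for (kind, idx), h in zip(names, half):
                if kind == "S":
                    amp_ci[idx] = self.amplitudes_[idx] + np.array([-h, h])
                elif kind == "T":
                    hl_ci[idx] = self.half_lives_[idx] + np.array([-h, h])
                else:
                    k_ci = self.constant_ + np.array([-h, h])
        elif method == "bootstrap":
            if seed is None:
                raise ValueError("bootstrap CIs require an explicit seed")
            rng = np.random.default_rng(seed)
            yhat = self.predict(X)
            # counting noise: var_i ∝ fitted rate, moment-matched to the
            # residual sum of squares with a dof correction
            c = float(resid @ resid) / max(float(np.sum(yhat)), 1e-300)
            c *= n / dof
            sd = np.sqrt(c * np.maximum(yhat, 0.0))
            se0 = self._parameter_se(X, y)
            t_stats: dict = {key: [] for key in se0}
            theta0 = self._param_value
            for _ in range(n_boot):
                # propagate the uncertainty of the estimated noise scale:
                # c itself is chi-square distributed with `dof` degrees of
                # freedom, so each replicate redraws it (the t-vs-z effect;
                # without this the intervals undercover at small n)
                scale_b = math.sqrt(dof / rng.chisquare(dof))
                y_star = np.clip(yhat + rng.normal(0.0, sd * scale_b), 0.0, None)
                b = self.__class__(**self.get_params()).fit(X, y_star)
                se_b = b._parameter_se(X, y_star)
                for key in t_stats:
                    if key in se_b and se_b[key] > 0:
                        t_stats[key].append(
                            (b._param_value(key) - theta0(key)) / se_b[key]
                        )
                    else:
                        t_stats[key].append(np.nan)
            for key, se in se0.items():
                ts = np.asarray(t_stats[key], dtype=float)
                ts = ts[np.isfinite(ts)]
                if len(ts) < max(20, n_boot // 4) or se == 0:
                    self.ci_reliable_ = False
                    continue
                q_lo, q_hi = np.percentile(ts, [2.5, 97.5])
                lo = theta0(key) - q_hi * se
                hi = theta0(key) - q_lo * se
                kind, idx = key
                if kind == "S":
                    amp_ci[idx] = (max(lo, 0.0), hi)
                elif kind == "T":
                    hl_ci[idx] = (max(lo, 0.0), hi)
                else:
                    k_ci = np.array([max(lo, 0.0), hi])
        else:
            raise ValueError(f"unknown CI method {method!r}")

        self.ci95_ = {
            "amplitudes": amp_ci,
            "half_lives": hl_ci,
            "constant": k_ci,
        }
        self.ci_method_ = method
        return self

    # -- export -------------------------------------------------------------

    def result_(self, X, y) -> FitResult:
        """Package the fitted state (and CIs, if estimated) as a FitResult."""
        self._check_fitted()
        X = np.asarray(X, dtype=float).reshape(-1, 2)
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(X)
        total = float(np.sum(self.amplitudes_))
        fractions = self.amplitudes_ / total if total > 0 else None
        scale = max(total, float(np.max(y, initial=0.0)), 1.0)
        identified = tuple(bool(s > _ZERO_ATOL * scale) for s in self.amplitudes_)
        return FitResult(
            amplitudes=self.amplitudes_.copy(),
            half_lives=self.half_lives_.copy(),
            constant=float(self.constant_),
            normalized_fractions=fractions,
            residuals=resid,
            sse=float(resid @ resid),
            mode=self._mode,
            labels=tuple(self.labels_),
            identified=identified,
            n_starts_used=getattr(self, "n_starts_used_", 1),
            ci95=dict(getattr(self, "ci95_", {})),
            ci_reliable=bool(getattr(self, "ci_reliable_", True)),
        )


class FixedHalfLifeFitter(_DecayFitterBase):
    """Amplitude estimation with the half-lives pinned to physical values.

    Parameters
    ----------
    half_lives : sequence of float
        The fixed half-lives in minutes (default: ¹¹C, ¹⁵O, ¹³N).
    labels : sequence of str or None
        Nuclide labels, one per component.
    fit_constant : bool
        Estimate the non-negative constant background K (default True).
    weighting : {"none", "poisson"}
        Residual weighting; "none" (ordinary least squares) is the default.

    The optimum is exact: the frame-averaged exponentials form a linear
    basis and the problem is non-negative linear least squares.
    """

    _mode = "fixed"

    def __init__(
        self,
        half_lives: Sequence[float] = PHYSICAL_HALF_LIVES,
        labels: Optional[Sequence[str]] = PHYSICAL_LABELS,
        fit_constant: bool = True,
        weighting: str = "none",
    ):
        self.half_lives = half_lives
        self.labels = labels
        self.fit_constant = fit_constant
        self.weighting = weighting

    def fit(self, X, y):
        half_lives = tuple(float(t) for t in self.half_lives)
        min_frames = len(half_lives) + 2
        X, y = _validate_xy(X, y, min_frames=min_frames)
        w = _weights(y, self.weighting)
        amps, K, resid, sse = _nnls_amplitudes(
            half_lives, X, y, self.fit_constant, w
        )
        self.amplitudes_ = amps
        self.constant_ = K
        self.half_lives_ = np.asarray(half_lives, dtype=float)
        self.labels_ = (
            tuple(self.labels)
            if self.labels is not None
            else (None,) * len(half_lives)
        )
        self.residuals_ = resid
        self.sse_ = sse
        self.n_frames_ = len(y)
        return self

    def _free_parameter_jacobian(self, X):
        cols = [frame_basis(self.half_lives_, X)]
        names = [("S", k) for k in range(len(self.half_lives_))]
        if self.fit_constant:
            cols.append(np.ones((X.shape[0], 1)))
            names.append(("K", 0))
        return np.column_stack(cols), names


class FreeHalfLifeFitter(_DecayFitterBase):
    """Joint amplitude and half-life estimation under non-negativity.

    A deterministic multi-start strategy tames the ill-conditioning:
    half-life start vectors are the physical values scaled per-component by
    ``start_scales``; at each start the amplitudes and K are warm-started
    from the exact fixed-half-life solve.  The lowest-SSE solution wins;
    ties go to the solution with fewer nonzero components.  Components are
    sorted by descending half-life.

    ``half_life_min`` (default 0.1 min) excludes the degenerate
    spike-at-zero solution; nothing faster is measurable on 2-min frames.
    """

    _mode = "free"

    def __init__(
        self,
        n_components: int = 3,
        half_life_inits: Sequence[float] = PHYSICAL_HALF_LIVES,
        start_scales: Sequence[float] = (0.5, 1.0, 2.0),
        half_life_min: float = 0.1,
        fit_constant: bool = True,
        weighting: str = "none",
        xtol: float = 1e-12,
    ):
        self.n_components = n_components
        self.half_life_inits = half_life_inits
        self.start_scales = start_scales
        self.half_life_min = half_life_min
        self.fit_constant = fit_constant
        self.weighting = weighting
        self.xtol = xtol

    def _start_half_lives(self) -> np.ndarray:
        inits = list(self.half_life_inits)[: self.n_components]
        while len(inits) < self.n_components:  # pad geometrically if asked for more
            inits.append(inits[-1] * 2.0 if inits else 2.0)
        return np.asarray(inits, dtype=float)

    def fit(self, X, y):
        n_comp = int(self.n_components)
        X, y = _validate_xy(X, y, min_frames=2 * n_comp + 1)
        if not self.half_life_min > 0:
            raise ValueError("half_life_min must be strictly positive")
        base = self._start_half_lives()
        if not np.any(y > 0):  # degenerate: nothing to fit, solution exact
            self.amplitudes_ = np.zeros(n_comp)
            self.half_lives_ = np.sort(base)[::-1]
            self.constant_ = 0.0
            self.labels_ = (None,) * n_comp
            self.residuals_ = np.zeros_like(y)
            self.sse_ = 0.0
            self.n_starts_used_ = 0
            self.n_frames_ = len(y)
            self.identified_ = np.zeros(n_comp, dtype=bool)
            return self
        w = _weights(y, self.weighting)
        sqrt_w = np.sqrt(w) if w is not None else None
        n_k = 1 if self.fit_constant else 0

        def residual(theta):
            amps, hls = theta[:n_comp], theta[n_comp : 2 * n_comp]
            K = theta[-1] if self.fit_constant else 0.0
            r = frame_basis(hls, X) @ amps + K - y
            return r * sqrt_w if sqrt_w is not None else r

        lower = np.concatenate(
            [np.zeros(n_comp), np.full(n_comp, self.half_life_min), np.zeros(n_k)]
        )
        upper = np.full(2 * n_comp + n_k, np.inf)

        best = None
        n_starts = 0
        failures = []
        for scales in itertools.product(self.start_scales, repeat=n_comp):
            h0 = np.maximum(base * np.asarray(scales), self.half_life_min)
            amps0, K0, _, _ = _nnls_amplitudes(h0, X, y, self.fit_constant, w)
            theta0 = np.concatenate([amps0, h0, [K0][:n_k]])
            n_starts += 1
            try:
                sol = optimize.least_squares(
                    residual,
                    theta0,
                    bounds=(lower, upper),
                    method="trf",
                    xtol=self.xtol,
                    ftol=self.xtol,
                    gtol=None,
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            r = sol.x  # unweighted sse is what we compare and report
            amps, hls = r[:n_comp], r[n_comp : 2 * n_comp]
            K = float(r[-1]) if self.fit_constant else 0.0
            resid_u = frame_basis(hls, X) @ amps + K - y
            sse = float(resid_u @ resid_u)
            nz = int(np.sum(amps > _ZERO_ATOL * max(float(np.max(y, initial=0)), 1)))
            cand = (sse, nz, amps, hls, K)
            if (
                best is None
                or sse < best[0] - 1e-15
                or (abs(sse - best[0]) <= 1e-15 and nz < best[1])
            ):
                best = cand
        if best is None:
            raise RuntimeError(
                f"free fit failed to converge from any of {n_starts} starts: "
                f"{failures[:3]}"
            )
        sse, _, amps, hls, K = best
        order = np.argsort(-hls)
        self.amplitudes_ = amps[order]
        self.half_lives_ = hls[order]
        self.constant_ = K
        self.labels_ = (None,) * n_comp
        resid = frame_basis(self.half_lives_, X) @ self.amplitudes_ + K - y
        self.residuals_ = resid
        self.sse_ = float(resid @ resid)
        self.n_starts_used_ = n_starts
        self.n_frames_ = len(y)
        scale = max(float(np.max(y, initial=0.0)), float(np.sum(amps)), 1.0)
        self.identified_ = self.amplitudes_ > _ZERO_ATOL * scale
        return self

    def _free_parameter_jacobian(self, X):
        """Numerical Jacobian w.r.t. the parameters of identified components."""
        names = []
        theta = []
        for k, s in enumerate(self.amplitudes_):
            names.append(("S", k))
            theta.append(s)
        for k, ident in enumerate(self.identified_):
            if ident:
                names.append(("T", k))
                theta.append(self.half_lives_[k])
        if self.fit_constant:
            names.append(("K", 0))
            theta.append(self.constant_)
        theta = np.asarray(theta, dtype=float)

        def predict_theta(th):
            amps = self.amplitudes_.copy()
            hls = self.half_lives_.copy()
            K = self.constant_
            for (kind, idx), v in zip(names, th):
                if kind == "S":
                    amps[idx] = v
                elif kind == "T":
                    hls[idx] = v
                else:
                    K = v
            return frame_basis(hls, X) @ amps + K

        eps = np.maximum(np.abs(theta), 1.0) * 1e-6
        base = predict_theta(theta)
        J = np.empty((X.shape[0], len(theta)))
        for j in range(len(theta)):
            tp = theta.copy()
            tp[j] += eps[j]
            J[:, j] = (predict_theta(tp) - base) / eps[j]
        return J, names


# ---------------------------------------------------------------------------
# functional wrappers over TAC objects


def _constraints_fixed_fitter(constraints: FitConstraints) -> FixedHalfLifeFitter:
    labels = PHYSICAL_LABELS if constraints.fixed_half_lives == PHYSICAL_HALF_LIVES \
        else None
    return FixedHalfLifeFitter(
        half_lives=constraints.fixed_half_lives,
        labels=labels,
        weighting=constraints.weighting,
    )


def fit_fixed(
    tac: TimeActivityCurve,
    schedule=None,
    constraints: Optional[FitConstraints] = None,
) -> FitResult:
    """Fixed-half-life fit of a TAC; exact non-negative linear LS optimum.

    ``schedule`` is accepted for interface symmetry; the frame bounds of
    the TAC itself define the design matrix.
    """
    constraints = constraints or FitConstraints(mode="fixed")
    if constraints.mode != "fixed":
        raise ValueError("fit_fixed requires constraints with mode='fixed'")
    est = _constraints_fixed_fitter(constraints)
    est.fit(tac.bounds_array, tac.values_array)
    return est.result_(tac.bounds_array, tac.values_array)


def fit_free(
    tac: TimeActivityCurve,
    schedule=None,
    constraints: Optional[FitConstraints] = None,
) -> FitResult:
    """Free-half-life fit of a TAC (multi-start bounded nonlinear LS)."""
    constraints = constraints or FitConstraints(mode="free")
    if constraints.mode != "free":
        raise ValueError("fit_free requires constraints with mode='free'")
    est = FreeHalfLifeFitter(
        n_components=constraints.n_components,
        half_life_min=constraints.half_life_lower_bound,
        weighting=constraints.weighting,
    )
    est.fit(tac.bounds_array, tac.values_array)
    return est.result_(tac.bounds_array, tac.values_array)


def normalize_amplitudes(result: FitResult) -> FitResult:
    """Recompute normalized_fractions = Sₖ/ΣSₖ (K excluded).

    ΣSₖ = 0 leaves the fractions flagged undefined (None) rather than
    raising.
    """
    total = float(np.sum(result.amplitudes))
    result.normalized_fractions = (
        result.amplitudes / total if total > 0 else None
    )
    return result


def _fitter_for_result(result: FitResult, constraints=None):
    if result.mode == "fixed":
        return FixedHalfLifeFitter(
            half_lives=tuple(result.half_lives), labels=result.labels
        )
    return FreeHalfLifeFitter(n_components=len(result.amplitudes))


def confidence_intervals(
    result: FitResult,
    tac: TimeActivityCurve,
    schedule=None,
    method: str = "linearized",
    n_boot: int = 200,
    seed: Optional[int] = None,
) -> FitResult:
    """Attach 95% CIs to a FitResult by refitting and propagating.

    See :meth:`_DecayFitterBase.estimate_confidence` for the two methods.
    """
    est = _fitter_for_result(result)
    est.fit(tac.bounds_array, tac.values_array)
    est.estimate_confidence(
        tac.bounds_array, tac.values_array, method=method, n_boot=n_boot, seed=seed
    )
    result.ci95 = est.ci95_
    result.ci_reliable = est.ci_reliable_
    return result


def grid_search_oracle(
    tac: TimeActivityCurve,
    schedule=None,
    half_life_grid: Sequence[float] = (),
    n_components: int = 3,
    fit_constant: bool = True,
    max_evaluations: int = 200_000,
) -> dict:
    """Exhaustive coarse-grid verification oracle for the free fit.

    Every combination (with repetition) of ``n_components`` half-lives from
    the grid is evaluated by the exact NNLS amplitude solve; the grid
    optimum is returned.  Deliberately brute force and independent of the
    nonlinear optimizer it checks.
    """
    grid = np.asarray(sorted(half_life_grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("half_life_grid must be non-empty and strictly positive")
    n_combos = math.comb(len(grid) + n_components - 1, n_components)
    if n_combos > max_evaluations:
        raise ValueError(
            f"grid too large: {n_combos} combinations exceed the "
            f"{max_evaluations} evaluation budget"
        )
    X = tac.bounds_array
    y = tac.values_array
    best = None
    for hls in itertools.combinations_with_replacement(grid, n_components):
        amps, K, _, sse = _nnls_amplitudes(hls, X, y, fit_constant)
        if best is None or sse < best["sse"]:
            order = np.argsort(-np.asarray(hls))
            best = {
                "amplitudes": amps[order],
                "half_lives": np.asarray(hls)[order],
                "constant": K,
                "sse": sse,
            }
    best["n_evaluations"] = n_combos
    return best
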