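"""Polynomial NARX models with a wavelet-network nonlinearity.

The model class predicts a continuous emotion-intensity trace ``y`` from its
own past values and from lagged exogenous physiological features ``u_m``.
The regressor vector at discrete time ``t`` is

    z(t) = [y(t-1), ..., y(t-n_y),
            u_1(t-n_k1), ..., u_1(t-n_k1-n_u1),
            u_1(t-n_k1)^2, ..., u_1(t-n_k1-n_u1)^2,
            ...,
            u_m(t-n_km), ..., u_m(t-n_km-n_um)^2]

i.e. output lags enter linearly while each exogenous feature contributes
``n_u + 1`` linear terms and their squares, starting at its own delay
``n_k``.  The one-step prediction is

    y(t) = y0 + (z(t) - zbar)' P l + W(z(t)) + S(z(t))

with output offset ``y0``, regressor mean ``zbar``, a projection matrix ``P``
(standardisation combined with a principal-axes rotation), linear weights
``l``, and the wavelet-network terms ``W`` (radial wavelet units) and ``S``
(radial scaling units) acting on the projected regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LagSpec",
    "NarxModel",
    "NarxResults",
    "NarxDivergenceError",
    "build_regressors",
    "fit_narx",
    "pearson_r",
]

#: Default admissible range for every integer lag parameter.
DEFAULT_BOUNDS = (1, 11)

#: Maximum number of exogenous features combined in one model.
MAX_FEATURES = 3


class NarxDivergenceError(RuntimeError):
    """Raised when a free-run simulation or generating recursion blows up."""


try:  # optional JIT for the scalar autoregressive loop of linear free runs
    from numba import njit as _njit

    @_njit(cache=False)
    def _ar_freerun(exo, beta_y, y_init, bound):  # pragma: no cover - jitted
        L = y_init.shape[0]
        T = L + exo.shape[0]
        y = np.empty(T)
        y[:L] = y_init
        ny = beta_y.shape[0]
        for t in range(L, T):
            val = exo[t - L]
            for i in range(ny):
                val += beta_y[i] * y[t - 1 - i]
            if not np.isfinite(val) or abs(val) > bound:
                return y, t
            y[t] = val
        return y, -1
except ImportError:  # pure-python fallback, identical semantics
    def _ar_freerun(exo, beta_y, y_init, bound):
        L = y_init.shape[0]
        T = L + exo.shape[0]
        y = np.empty(T)
        y[:L] = y_init
        ny = beta_y.shape[0]
        for t in range(L, T):
            val = exo[t - L] + float(beta_y @ y[t - ny:t][::-1])
            if not np.isfinite(val) or abs(val) > bound:
                return y, t
            y[t] = val
        return y, -1


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation, with the convention that a zero-variance
    series correlates 0 with anything (degenerate predictions score 0, they
    are neither rewarded nor excluded)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        return 0.0
    return float(da @ db / np.sqrt(va * vb))


@dataclass(frozen=True)
class LagSpec:
    """Integer lag structure of a NARX model.

    Parameters
    ----------
    n_y : output lag count (>= 1).
    features : names of the exogenous features, at most 3.
    n_u : per-feature input lag count; feature m contributes n_u[m] + 1
        lagged terms.
    n_k : per-feature input delay (>= 1; the current input u(t) never
        enters).
    """

    n_y: int
    features: tuple[str, ...]
    n_u: tuple[int, ...]
    n_k: tuple[int, ...]
    bounds: tuple[int, int] = DEFAULT_BOUNDS

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "n_u", tuple(int(v) for v in self.n_u))
        object.__setattr__(self, "n_k", tuple(int(v) for v in self.n_k))
        m = len(self.features)
        if not 1 <= m <= MAX_FEATURES:
            raise ValueError(f"need 1..{MAX_FEATURES} features, got {m}")
        if len(self.n_u) != m or len(self.n_k) != m:
            raise ValueError("features, n_u and n_k must have equal length")
        lo, hi = self.bounds
        for v in (self.n_y, *self.n_u, *self.n_k):
            if not lo <= int(v) <= hi:
                raise ValueError(f"lag parameter {v} outside bounds [{lo}, {hi}]")

    @property
    def max_lookback(self) -> int:
        return max(self.n_y, max(k + u for k, u in zip(self.n_k, self.n_u)))

    @property
    def n_params(self) -> int:
        """Free integer parameters: n_y plus (n_u, n_k) per feature."""
        return 1 + 2 * len(self.features)

    def as_vector(self) -> tuple[int, ...]:
        """(n_y, n_u1, n_k1, ..., n_um, n_km) — the chromosome layout."""
        out = [self.n_y]
        for u, k in zip(self.n_u, self.n_k):
            out += [u, k]
        return tuple(out)

    @classmethod
    def from_vector(cls, vec: Sequence[int], features: Sequence[str],
                    bounds=DEFAULT_BOUNDS) -> "LagSpec":
        vec = [int(v) for v in vec]
        m = len(features)
        if len(vec) != 1 + 2 * m:
            raise ValueError("vector length does not match feature count")
        return cls(vec[0], tuple(features), tuple(vec[1::2]), tuple(vec[2::2]),
                   bounds=tuple(bounds))

    def column_names(self) -> list[str]:
        names = [f"y(t-{i})" for i in range(1, self.n_y + 1)]
        for name, u, k in zip(self.features, self.n_u, self.n_k):
            lags = range(k, k + u + 1)
            names += [f"{name}(t-{i})" for i in lags]
            names += [f"{name}(t-{i})^2" for i in lags]
        return names


def build_regressors(
    y: np.ndarray,
    u: Mapping[str, np.ndarray],
    spec: LagSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the regressor matrix and target vector for one trial.

    Rows cover t = L .. T-1 with L the maximum lookback, so the row count is
    T - max(n_y, max_m(n_k_m + n_u_m)).  Trials are never concatenated: call
    per trial and pool the results.

    Returns ``(Z, target)`` where ``Z[i]`` is z(t=L+i) and ``target[i]`` is
    y(t=L+i).
    """
    y = np.asarray(y, dtype=float)
    T = y.shape[0]
    L = spec.max_lookback
    if T <= L:
        raise ValueError(f"series of length {T} too short for lookback {L}")
    cols: list[np.ndarray] = []
    for i in range(1, spec.n_y + 1):
        cols.append(y[L - i:T - i])
    for name, nu, nk in zip(spec.features, spec.n_u, spec.n_k):
        try:
            series = np.asarray(u[name], dtype=float)
        except KeyError:
            raise KeyError(f"feature {name!r} not available") from None
        if series.shape[0] != T:
            raise ValueError(f"feature {name!r} length {series.shape[0]} != {T}")
        if not np.all(np.isfinite(series)):
            raise ValueError(f"feature {name!r} contains non-finite values")
        lin = [series[L - lag:T - lag] for lag in range(nk, nk + nu + 1)]
        cols.extend(lin)
        cols.extend(c * c for c in lin)
    Z = np.column_stack(cols)
    return Z, y[L:].copy()


@dataclass
class _RadialUnits:
    """Dilated/translated radial units on the projected regressor space.

    kind 0 is a scaling unit phi(rho) = exp(-rho/2); kind 1 a wavelet unit
    psi(rho) = (d - rho) exp(-rho/2), with rho the squared radial combination
    ||a * (x - c)||^2 of the projected regressors x.
    """

    kinds: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    amps: np.ndarray = field(default_factory=lambda: np.zeros(0))
    centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    inv_scales: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __len__(self) -> int:
        return int(self.kinds.shape[0])

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Sum of all unit responses at each row of X (n, d) -> (n,)."""
        if len(self) == 0:
            return np.zeros(X.shape[0])
        d = X.shape[1]
        out = np.zeros(X.shape[0])
        for kind, amp, c, a in zip(self.kinds, self.amps, self.centers,
                                   self.inv_scales):
            rho = np.square((X - c) * a).sum(axis=1)
            g = np.exp(-0.5 * rho)
            out += amp * ((d - rho) * g if kind else g)
        return out


def _unit_column(X: np.ndarray, kind: int, c: np.ndarray,
                 a: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    rho = np.square((X - c) * a).sum(axis=1)
    g = np.exp(-0.5 * rho)
    return (d - rho) * g if kind else g


def _fit_units(
    X: np.ndarray,
    resid: np.ndarray,
    n_units: int,
    rng: np.random.Generator,
    n_centers: int,
    dilations: Sequence[float],
    min_improvement: float,
) -> tuple[_RadialUnits, np.ndarray]:
    """Greedy matching-pursuit fit of radial wavelet/scaling units.

    Candidate units sit on a seeded subsample of training points at dyadic
    dilations of the per-dimension spread; amplitudes of the selected set are
    refitted jointly by least squares after each addition.  Stops early when
    the relative residual-variance improvement drops below
    ``min_improvement``.
    """
    n, d = X.shape
    units = _RadialUnits(centers=np.zeros((0, d)), inv_scales=np.zeros((0, d)))
    if n_units <= 0 or n < 4:
        return units, resid
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    idx = rng.choice(n, size=min(n_centers, n), replace=False)
    cands: list[tuple[int, np.ndarray, np.ndarray]] = []
    cols = []
    for s in dilations:
        a = 1.0 / (s * sd)
        for i in idx:
            for kind in (0, 1):
                cands.append((kind, X[i].copy(), a))
                cols.append(_unit_column(X, kind, X[i], a))
    B = np.column_stack(cols)
    norms = np.linalg.norm(B, axis=0)
    norms[norms == 0] = np.inf

    chosen: list[int] = []
    r = resid.copy()
    sse = float(r @ r)
    basis = np.empty((n, 0))
    amps = np.zeros(0)
    for _ in range(n_units):
        score = np.abs(B.T @ r) / norms
        if chosen:
            score[chosen] = -np.inf
        j = int(np.argmax(score))
        trial_basis = np.column_stack([basis, B[:, j]])
        amps_new, *_ = np.linalg.lstsq(trial_basis, resid, rcond=None)
        r_new = resid - trial_basis @ amps_new
        sse_new = float(r_new @ r_new)
        if sse <= 0 or (sse - sse_new) / sse < min_improvement:
            break
        chosen.append(j)
        basis, amps, r, sse = trial_basis, amps_new, r_new, sse_new
    if chosen:
        units = _RadialUnits(
            kinds=np.array([cands[j][0] for j in chosen], dtype=np.int8),
            amps=np.asarray(amps, dtype=float),
            centers=np.vstack([cands[j][1] for j in chosen]),
            inv_scales=np.vstack([cands[j][2] for j in chosen]),
        )
    return units, r


@dataclass
class NarxResults:
    """Fitted NARX predictor; stores everything needed for exact
    re-evaluation of y(t) = y0 + (z - zbar)' P l + W(z) + S(z)."""

    spec: LagSpec
    y0: float
    zbar: np.ndarray
    scale: np.ndarray          # per-column standard deviations of z
    rotation: np.ndarray       # principal axes V (p, q) of the standardised z
    linear_weights: np.ndarray
    units: _RadialUnits
    resid_var: float
    n_obs: int
    seed: int | None = None

    @property
    def projection(self) -> np.ndarray:
        """The projection matrix P = diag(1/scale) V."""
        return self.rotation / self.scale[:, None]

    def _project(self, Z: np.ndarray) -> np.ndarray:
        return ((Z - self.zbar) / self.scale) @ self.rotation

    def predict_regressors(self, Z: np.ndarray) -> np.ndarray:
        X = self._project(Z)
        return self.y0 + X @ self.linear_weights + self.units.evaluate(X)

    def predict(self, y: np.ndarray, u: Mapping[str, np.ndarray]) -> np.ndarray:
        """One-step-ahead prediction: all output lags from ground truth.

        Returns the predicted series for t = max_lookback .. T-1.
        """
        Z, _ = build_regressors(y, u, self.spec)
        return self.predict_regressors(Z)

    def simulate(
        self,
        y: np.ndarray,
        u: Mapping[str, np.ndarray],
        mode: str = "free-run",
        divergence_bound: float = 1e3,
        y_init: np.ndarray | None = None,
    ) -> np.ndarray:
        """Simulate on a test trial.

        In ``free-run`` mode the output lags are taken from the model's own
        previous predictions; the first ``max_lookback`` samples come from
        ``y_init`` (defaults to the ground-truth start of ``y``).  In
        ``one-step`` mode all output lags come from the ground truth.
        Returns the prediction for t = max_lookback .. T-1.
        """
        if mode == "one-step":
            return self.predict(y, u)
        if mode != "free-run":
            raise ValueError(f"unknown mode {mode!r}")
        y = np.asarray(y, dtype=float)
        spec = self.spec
        L = spec.max_lookback
        T = y.shape[0]
        if T <= L:
            raise ValueError("test trial shorter than the model lookback")
        series = {n: np.asarray(u[n], dtype=float) for n in spec.features}
        if len(self.units) == 0:
            # without wavelet units the prediction is affine in z, so the
            # exogenous contribution is a fixed series and only a scalar
            # autoregressive loop remains
            beta = (self.rotation @ self.linear_weights) / self.scale
            c = self.y0 - float(self.zbar @ beta)
            beta_y = beta[:spec.n_y]
            exo = np.full(T - L, c)
            pos = spec.n_y
            for name, nu, nk in zip(spec.features, spec.n_u, spec.n_k):
                s = series[name]
                for j, lag in enumerate(range(nk, nk + nu + 1)):
                    seg = s[L - lag:T - lag]
                    exo += beta[pos + j] * seg
                    exo += beta[pos + nu + 1 + j] * seg * seg
                pos += 2 * (nu + 1)
            init = (np.asarray(y_init, dtype=float)[:L]
                    if y_init is not None else y[:L])
            yhat, bad_t = _ar_freerun(exo, np.ascontiguousarray(beta_y),
                                      np.ascontiguousarray(init),
                                      divergence_bound)
            if bad_t >= 0:
                raise NarxDivergenceError(
                    f"free-run diverged at t={bad_t}: |yhat| exceeds "
                    f"{divergence_bound}")
            return yhat[L:]
        yhat = np.empty(T)
        yhat[:L] = np.asarray(y_init, dtype=float)[:L] if y_init is not None else y[:L]
        w = self.linear_weights
        V = self.rotation
        zbar, sc = self.zbar, self.scale
        has_units = len(self.units) > 0
        p = zbar.shape[0]
        z = np.empty(p)
        for t in range(L, T):
            pos = 0
            z[pos:pos + spec.n_y] = yhat[t - spec.n_y:t][::-1]
            pos += spec.n_y
            for name, nu, nk in zip(spec.features, spec.n_u, spec.n_k):
                seg = series[name][t - nk - nu:t - nk + 1][::-1]
                z[pos:pos + nu + 1] = seg
                z[pos + nu + 1:pos + 2 * (nu + 1)] = seg * seg
                pos += 2 * (nu + 1)
            x = ((z - zbar) / sc) @ V
            val = self.y0 + x @ w
            if has_units:
                val += float(self.units.evaluate(x[None, :])[0])
            if not np.isfinite(val) or abs(val) > divergence_bound:
                raise NarxDivergenceError(
                    f"free-run diverged at t={t}: |yhat|={val!r} exceeds "
                    f"{divergence_bound}")
            yhat[t] = val
        return yhat[L:]

    def score(self, y, u, mode: str = "free-run") -> float:
        """Correlation between the simulated output and the ground truth."""
        pred = self.simulate(y, u, mode=mode)
        return pearson_r(pred, np.asarray(y, dtype=float)[self.spec.max_lookback:])

    def save(self, path) -> None:
        np.savez(
            path,
            n_y=self.spec.n_y,
            features=np.array(self.spec.features),
            n_u=np.array(self.spec.n_u),
            n_k=np.array(self.spec.n_k),
            bounds=np.array(self.spec.bounds),
            y0=self.y0,
            zbar=self.zbar,
            scale=self.scale,
            rotation=self.rotation,
            linear_weights=self.linear_weights,
            unit_kinds=self.units.kinds,
            unit_amps=self.units.amps,
            unit_centers=self.units.centers,
            unit_inv_scales=self.units.inv_scales,
            resid_var=self.resid_var,
            n_obs=self.n_obs,
            seed=-1 if self.seed is None else self.seed,
        )

    @classmethod
    def load(cls, path) -> "NarxResults":
        with np.load(path, allow_pickle=False) as f:
            spec = LagSpec(
                int(f["n_y"]),
                tuple(str(s) for s in f["features"]),
                tuple(int(v) for v in f["n_u"]),
                tuple(int(v) for v in f["n_k"]),
                bounds=tuple(int(v) for v in f["bounds"]),
            )
            units = _RadialUnits(
                kinds=f["unit_kinds"],
                amps=f["unit_amps"],
                centers=f["unit_centers"],
                inv_scales=f["unit_inv_scales"],
            )
            seed = int(f["seed"])
            return cls(
                spec=spec,
                y0=float(f["y0"]),
                zbar=f["zbar"],
                scale=f["scale"],
                rotation=f["rotation"],
                linear_weights=f["linear_weights"],
                units=units,
                resid_var=float(f["resid_var"]),
                n_obs=int(f["n_obs"]),
                seed=None if seed < 0 else seed,
            )

    def summary(self) -> str:
        spec = self.spec
        lines = [
            "NARX wavelet-network model",
            "=" * 40,
            f"output lags n_y        : {spec.n_y}",
        ]
        for name, nu, nk in zip(spec.features, spec.n_u, spec.n_k):
            lines.append(f"feature {name:<18}: n_u={nu:<3} n_k={nk}")
        lines += [
            f"regressor columns      : {self.zbar.shape[0]}",
            f"projected dimensions   : {self.rotation.shape[1]}",
            f"wavelet/scaling units  : {len(self.units)}",
            f"offset y0              : {self.y0:.6g}",
            f"training observations  : {self.n_obs}",
            f"training resid variance: {self.resid_var:.6g}",
        ]
        return "\n".join(lines)


def fit_narx(
    trial_data: Sequence[tuple[np.ndarray, np.ndarray]],
    spec: LagSpec,
    n_units: int = 8,
    seed: int | None = 0,
    n_centers: int = 32,
    dilations: Sequence[float] = (1.0, 0.5, 0.25),
    min_improvement: float = 1e-4,
    var_keep: float = 1.0 - 1e-6,
) -> NarxResults:
    """Fit from prebuilt per-trial ``(Z, target)`` pairs (see
    :func:`build_regressors`); trials are pooled but never concatenated
    across their boundary."""
    if not trial_data:
        raise ValueError("need at least one training trial")
    Z = np.concatenate([z for z, _ in trial_data], axis=0)
    y = np.concatenate([t for _, t in trial_data])
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regressors or targets")
    n, p = Z.shape
    y0 = float(y.mean())
    zbar = Z.mean(axis=0)
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    Zs = (Z - zbar) / scale
    # principal axes of the standardised regressors, keeping components
    # explaining >= var_keep of the variance (rank-deficiency is handled by
    # dropping null directions, which makes the least squares minimum-norm)
    C = (Zs.T @ Zs) / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        q = 1
    else:
        cum = np.cumsum(evals) / total
        q = int(np.searchsorted(cum, var_keep) + 1)
        q = min(q, int((evals > 1e-12 * evals[0]).sum()) or 1)
    V = evecs[:, :q]
    X = Zs @ V
    yc = y - y0
    # X columns are orthogonal (X'X = n * diag(evals)): solve directly
    denom = n * evals[:q]
    denom[denom == 0] = np.inf
    l = (X.T @ yc) / denom
    resid = yc - X @ l
    rng = np.random.default_rng(seed)
    units, resid = _fit_units(X, resid, n_units, rng, n_centers, dilations,
                              min_improvement)
    return NarxResults(
        spec=spec,
        y0=y0,
        zbar=zbar,
        scale=scale,
        rotation=V,
        linear_weights=l,
        units=units,
        resid_var=float(resid @ resid / n),
        n_obs=n,
        seed=seed,
    )


class NarxModel:
    """NARX model bound to training data, statsmodels-style.

    Parameters
    ----------
    endog : sequence of per-trial intensity arrays (never concatenated
        across trial boundaries).
    exog : sequence of per-trial feature mappings ``{name: array}``.
    spec : the integer lag structure.
    n_units : maximum number of wavelet/scaling units (0 disables the
        wavelet network, reducing the model to polynomial least squares).
    """

    def __init__(self, endog, exog, spec: LagSpec, *, n_units: int = 8,
                 n_centers: int = 32, dilations: Sequence[float] = (1.0, 0.5, 0.25),
                 min_improvement: float = 1e-4):
        if len(endog) != len(exog) or len(endog) == 0:
            raise ValueError("need matching, non-empty endog/exog trial lists")
        self.spec = spec
        self.n_units = n_units
        self.n_centers = n_centers
        self.dilations = tuple(dilations)
        self.min_improvement = min_improvement
        self._trial_data = [build_regressors(y, u, spec)
                            for y, u in zip(endog, exog)]

    @classmethod
    def from_feature_sets(cls, feature_sets, spec: LagSpec, **kwargs) -> "NarxModel":
        """Build from :class:`~emonarx.features.FeatureSet` objects."""
        endog = [fs.intensity for fs in feature_sets]
        exog = [fs.features for fs in feature_sets]
        for fs in feature_sets:
            for name in spec.features:
                if not fs.available.get(name, False):
                    raise ValueError(
                        f"feature {name!r} is masked in trial "
                        f"{getattr(fs, 'trial', '?')}")
        return cls(endog, exog, spec, **kwargs)

    def fit(self, seed: int | None = 0) -> NarxResults:
        return fit_narx(
            self._trial_data, self.spec, n_units=self.n_units, seed=seed,
            n_centers=self.n_centers, dilations=self.dilations,
            min_improvement=self.min_improvement)
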