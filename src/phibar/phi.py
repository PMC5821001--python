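"""Integrated information from multichannel time series.

Given a stationary multichannel signal, the effective information of a
bipartition {M1, M2} at lag tau is the log-det difference between the parts'
and the whole's linear prediction-error covariances,

    phi(M1, M2) = sum_k 1/2 log det Sigma(E^{Mk}) - 1/2 log det Sigma(E^X),

with E the residual of the regression X_t = alpha + A X_{t-tau} + E_t
restricted to each channel subset (the "AR" estimator), or the conditional
covariance Sigma(X_{t-tau} | X_t) in place of the residual covariance (the
Gaussian "E" estimator).  The integrated information Phi of a channel unit
is phi at the minimum-information partition (MIP), found by exhaustive
search over all distinct bipartitions.

Because the MIP search is super-exponential in the number of channels, the
practical estimator averages Phi over many small random channel subsets
("sample units", default 8 channels x 600 units) and subtracts, per unit,
the median Phi of shuffle surrogates that destroy cross-channel phase
relations:

    phi_bar = mean_i Phi_i  -  mean_i median(Phi_surr_i).

All log-dets use natural logarithms; phi is reported in nats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import ConfigurationError, EpochSet, IngestionError, TimeSeriesMatrix
from .partitions import Bipartition, _partition_tables, enumerate_bipartitions

logger = logging.getLogger(__name__)

__all__ = [
    "LaggedMoments", "ARFit", "PhiUnitResult", "SampleUnitSet", "PhiBarEstimate",
    "ReliabilityCurve", "RegionalPhiMap", "lagged_moments", "ar_fit", "phi_ar",
    "phi_e", "min_information_partition", "draw_sample_units", "surrogate_shuffle",
    "phi_bar", "reliability_curve", "regional_phi", "PhiBarModel", "PhiBarResults",
]

RIDGE_DEFAULT = 1e-8
RIDGE_MAX = 1e-4


class DegenerateCovarianceError(np.linalg.LinAlgError):
    """Covariance not positive definite even after maximal regularization."""


# --------------------------------------------------------------------------
# moments
# --------------------------------------------------------------------------

@dataclass
class LaggedMoments:
    """Pooled second moments of (X_t, X_{t-tau}).

    ``cov0`` is the marginal covariance of the present samples, ``cov0_past``
    of the lagged samples (they differ only by finite-sample edge effects),
    and ``cov_tau[i, j] = Cov(X_t[i], X_{t-tau}[j])``.  Moments are pooled
    across epochs after per-epoch mean removal; lagged pairs never straddle
    epoch boundaries.
    """

    tau: int
    cov0: np.ndarray
    cov0_past: np.ndarray
    cov_tau: np.ndarray
    nobs: int
    mean_present: np.ndarray
    mean_past: np.ndarray
    channel_labels: list[str] | None = None

    @property
    def n_channels(self) -> int:
        return self.cov0.shape[0]


def lagged_moments(epochs: EpochSet | TimeSeriesMatrix, tau: int = 1) -> LaggedMoments:
    """Estimate lag-``tau`` second moments pooled over epochs."""
    if tau < 1:
        raise ConfigurationError("tau must be >= 1 sample")
    if isinstance(epochs, TimeSeriesMatrix):
        blocks = [epochs.data]
        labels = epochs.channel_labels
    else:
        blocks = [ep.data for ep in epochs.epochs]
        labels = epochs.channel_labels
    c = blocks[0].shape[0]
    spp = np.zeros((c, c))
    smm = np.zeros((c, c))
    spm = np.zeros((c, c))
    sp = np.zeros(c)
    sm = np.zeros(c)
    nobs = 0
    for x in blocks:
        if x.shape[1] <= tau:
            raise ConfigurationError("epoch shorter than lag tau")
        xp = x[:, tau:]
        xm = x[:, :-tau]
        xp = xp - xp.mean(axis=1, keepdims=True)
        xm = xm - xm.mean(axis=1, keepdims=True)
        spp += xp @ xp.T
        smm += xm @ xm.T
        spm += xp @ xm.T
        sp += x[:, tau:].mean(axis=1) * xp.shape[1]
        sm += x[:, :-tau].mean(axis=1) * xm.shape[1]
        nobs += xp.shape[1]
    if nobs <= c:
        raise ConfigurationError(f"only {nobs} lagged samples for {c} channels")
    return LaggedMoments(tau=tau, cov0=spp / nobs, cov0_past=smm / nobs,
                         cov_tau=spm / nobs, nobs=nobs,
                         mean_present=sp / nobs, mean_past=sm / nobs,
                         channel_labels=list(labels) if labels else None)


# --------------------------------------------------------------------------
# regression and effective information
# --------------------------------------------------------------------------

@dataclass
class ARFit:
    """Lag-tau linear regression restricted to a channel subset."""

    subset: tuple[int, ...]
    tau: int
    A: np.ndarray
    alpha: np.ndarray
    resid_cov: np.ndarray
    ridge_used: float = 0.0


def _ridge_solve(M: np.ndarray, B: np.ndarray, ridge: float) -> tuple[np.ndarray, float]:
    """Solve M W = B for SPD-intended M, escalating a relative ridge if needed."""
    lam = 0.0
    bump = max(np.trace(M) / len(M), np.finfo(float).tiny)
    while True:
        try:
            L = np.linalg.cholesky(M + lam * bump * np.eye(len(M)))
            W = np.linalg.solve(L.T, np.linalg.solve(L, B))
            return W, lam
        except np.linalg.LinAlgError:
            lam = ridge if lam == 0.0 else lam * 10
            if lam > RIDGE_MAX:
                raise DegenerateCovarianceError(
                    "covariance not PD after maximal ridge regularization"
                )
            logger.warning("ridge escalated to %.1e * trace/dim", lam)


def ar_fit(moments: LaggedMoments, subset: tuple[int, ...] | list[int],
           ridge: float = RIDGE_DEFAULT) -> ARFit:
    """Fit X_t = alpha + A X_{t-tau} + E on a channel subset from moments.

    The residual covariance is the Schur complement
    ``cov0[S] - cov_tau[S] cov0_past[S]^-1 cov_tau[S]^T``.
    """
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ConfigurationError("subset must be nonempty")
    ix = np.asarray(subset)
    P = moments.cov0[np.ix_(ix, ix)]
    M = moments.cov0_past[np.ix_(ix, ix)]
    C = moments.cov_tau[np.ix_(ix, ix)]
    # near-singular regressor covariance (duplicated or silent channels)
    # takes the ridge path even when Cholesky would numerically succeed
    if len(ix) > 1 and np.linalg.cond(M) > 1e10:
        bump = np.trace(M) / len(M)
        W, lam = _ridge_solve(M + ridge * bump * np.eye(len(M)), C.T, ridge)
        lam = max(lam, ridge)
        logger.warning("ill-conditioned covariance on subset %s: ridge %.1e", subset, lam)
    else:
        W, lam = _ridge_solve(M, C.T, ridge)
    A = W.T
    resid = P - C @ W
    resid = (resid + resid.T) / 2
    alpha = moments.mean_present[ix] - A @ moments.mean_past[ix]
    if lam:
        logger.warning("ar_fit on subset %s used ridge %.1e", subset, lam)
    return ARFit(subset=subset, tau=moments.tau, A=A, alpha=alpha,
                 resid_cov=resid, ridge_used=lam)


def _oriented(moments: LaggedMoments, estimator: str):
    """Map an estimator name to (present, past, cross) matrices.

    "ar": residual of predicting X_t from X_{t-tau};
    "e":  conditional covariance of X_{t-tau} given X_t (Gaussian form) —
    the same Schur complement with the roles of the two marginals swapped.
    """
    est = estimator.lower()
    if est == "ar":
        return moments.cov0, moments.cov0_past, moments.cov_tau
    if est == "e":
        return moments.cov0_past, moments.cov0, moments.cov_tau.T
    raise ConfigurationError(f"unknown estimator {estimator!r} (use 'ar' or 'e')")


def _batch_subset_logdets(P, M, C, units, ridge):
    """Log-det of the Schur-complement residual covariance for every nonempty
    subset of every unit.

    Parameters are the full (n_channels, n_channels) moment matrices, and
    ``units`` an (U, n) integer array of channel indices.  Returns an
    (U, 2**n) array ``ld`` with ``ld[u, bits(S)]`` filled for each subset S
    (positions within the unit), and the total number of ridge escalations.
    """
    subsets, _, full_bits, _ = _partition_tables(units.shape[1])
    U, n = units.shape
    Pu = P[units[:, :, None], units[:, None, :]]
    Mu = M[units[:, :, None], units[:, None, :]]
    Cu = C[units[:, :, None], units[:, None, :]]
    ld = np.full((U, full_bits + 1), np.nan)
    n_escal = 0
    eye_cache = {}
    for s, (idx, bits) in subsets.items():
        rows = idx[:, :, None]
        cols = idx[:, None, :]
        Ms = Mu[:, rows, cols]
        Ps = Pu[:, rows, cols]
        Cs = Cu[:, rows, cols]
        if s not in eye_cache:
            eye_cache[s] = np.eye(s)
        eye = eye_cache[s]
        lam = 0.0
        while True:
            try:
                Mreg = Ms if lam == 0.0 else Ms + (
                    lam * np.trace(Ms, axis1=-2, axis2=-1)[..., None, None] / s) * eye
                W = np.linalg.solve(Mreg, np.swapaxes(Cs, -2, -1))
                resid = Ps - Cs @ W
                resid = (resid + np.swapaxes(resid, -2, -1)) / 2
                if lam > 0.0:
                    resid = resid + (
                        lam * np.trace(resid, axis1=-2, axis2=-1)[..., None, None] / s) * eye
                sign, logdet = np.linalg.slogdet(resid)
                if np.all(sign > 0):
                    break
                raise np.linalg.LinAlgError("non-positive determinant")
            except np.linalg.LinAlgError:
                lam = ridge if lam == 0.0 else lam * 10
                n_escal += 1
                if lam > RIDGE_MAX:
                    raise DegenerateCovarianceError(
                        f"size-{s} subset covariance not PD after maximal ridge"
                    )
        ld[:, bits] = logdet
    if n_escal:
        logger.warning("subset log-det kernel escalated ridge %d time(s)", n_escal)
    return ld


def _phi_all_partitions(moments: LaggedMoments, units: np.ndarray, estimator: str,
                        ridge: float = RIDGE_DEFAULT, chunk: int = 256) -> np.ndarray:
    # chunk=256 keeps the per-size gather temporaries inside L2/L3 cache;
    # large chunks cost ~70% more wall time on one core
    """phi of every distinct bipartition for each unit: (U, n_partitions)."""
    P, M, C = _oriented(moments, estimator)
    n = units.shape[1]
    _, pair_bits, full_bits, _ = _partition_tables(n)
    out = np.empty((units.shape[0], pair_bits.shape[0]))
    for lo in range(0, units.shape[0], chunk):
        u = units[lo:lo + chunk]
        ld = _batch_subset_logdets(P, M, C, u, ridge)
        out[lo:lo + len(u)] = 0.5 * (
            ld[:, pair_bits[:, 0]] + ld[:, pair_bits[:, 1]] - ld[:, [full_bits]]
        )
    if not np.isfinite(out).all():
        bad = np.argwhere(~np.isfinite(out))[0]
        part = enumerate_bipartitions(n)[bad[1]]
        raise IngestionError(f"non-finite phi at unit {bad[0]}, partition {part}")
    return out


def _phi_min(moments, units, estimator, normalize=False, ridge=RIDGE_DEFAULT):
    """Minimum-phi (Phi) and MIP index per unit."""
    phis = _phi_all_partitions(moments, units, estimator, ridge)
    if normalize:
        _, _, _, norm = _partition_tables(units.shape[1])
        key = phis / norm
    else:
        key = phis
    mip = np.argmin(key, axis=1)
    return phis[np.arange(len(phis)), mip], mip


def phi_ar(moments: LaggedMoments, bipartition: Bipartition,
           unit: tuple[int, ...] | None = None, ridge: float = RIDGE_DEFAULT) -> float:
    """Effective information (AR form) of one bipartition, in nats.

    ``bipartition`` indexes positions within ``unit`` (default: all channels
    of ``moments`` in order).
    """
    return _phi_single(moments, bipartition, "ar", unit, ridge)


def phi_e(moments: LaggedMoments, bipartition: Bipartition,
          unit: tuple[int, ...] | None = None, ridge: float = RIDGE_DEFAULT) -> float:
    """Effective information (Gaussian conditional-covariance form), in nats."""
    return _phi_single(moments, bipartition, "e", unit, ridge)


def _phi_single(moments, bipartition, estimator, unit, ridge):
    if unit is None:
        unit = tuple(range(moments.n_channels))
    unit = np.asarray(unit)[None, :]
    P, M, C = _oriented(moments, estimator)
    ld = _batch_subset_logdets(P, M, C, unit, ridge)

    def bits(t):
        b = 0
        for i in t:
            b |= 1 << i
        return b

    full = 2 ** unit.shape[1] - 1
    val = 0.5 * (ld[0, bits(bipartition.part1)] + ld[0, bits(bipartition.part2)]
                 - ld[0, full])
    if not np.isfinite(val):
        raise IngestionError(f"non-finite phi for partition {bipartition}")
    return float(val)


@dataclass
class PhiUnitResult:
    """Exhaustive bipartition search result for one channel unit."""

    unit: tuple[int, ...]
    phi_by_partition: dict[Bipartition, float]
    mip: Bipartition
    phi: float
    estimator: str


def min_information_partition(moments: LaggedMoments, unit: tuple[int, ...] | list[int],
                              estimator: str = "ar", normalize: bool = False,
                              ridge: float = RIDGE_DEFAULT) -> PhiUnitResult:
    """Exhaustive MIP search over all distinct bipartitions of ``unit``.

    Ties break on canonical partition order.  With ``normalize=True`` the
    argmin is taken over phi / min(|part|) but the reported phi is always
    unnormalized.
    """
    unit = tuple(int(i) for i in unit)
    units = np.asarray(unit)[None, :]
    phis = _phi_all_partitions(moments, units, estimator, ridge)[0]
    parts = enumerate_bipartitions(len(unit))
    if normalize:
        _, _, _, norm = _partition_tables(len(unit))
        mip_idx = int(np.argmin(phis / norm))
    else:
        mip_idx = int(np.argmin(phis))
    return PhiUnitResult(
        unit=unit,
        phi_by_partition={p: float(v) for p, v in zip(parts, phis)},
        mip=parts[mip_idx], phi=float(phis[mip_idx]), estimator=estimator.upper(),
    )


# --------------------------------------------------------------------------
# sample units and surrogates
# --------------------------------------------------------------------------

@dataclass
class SampleUnitSet:
    """k random n-channel subsets of the channel pool (indices, sorted)."""

    n: int
    k: int
    units: np.ndarray  # (k, n) int
    seed: int | None = None


def draw_sample_units(channel_pool: int | list, n: int = 8, k: int = 600,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> SampleUnitSet:
    """Draw ``k`` units of ``n`` distinct channels uniformly from the pool.

    Channels never repeat within a unit; units may overlap.  Intended to be
    drawn once (on the baseline state) and reused across states.
    """
    pool = channel_pool if isinstance(channel_pool, int) else len(channel_pool)
    if pool < n:
        raise ConfigurationError(f"pool of {pool} channels cannot supply units of {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    units = np.empty((k, n), dtype=np.int64)
    for i in range(k):
        units[i] = np.sort(rng.choice(pool, size=n, replace=False))
    return SampleUnitSet(n=n, k=k, units=units, seed=seed)


def surrogate_shuffle(epochs: EpochSet, n_surrogates: int = 20,
                      seed: int | None = None) -> list[EpochSet]:
    """Split-and-swap (circular shift) surrogates, independently per channel.

    Within each epoch and channel a random split sample is chosen and the
    two segments are swapped.  The per-channel amplitude distribution is
    exactly preserved and the spectrum approximately so, while cross-channel
    phase relations are destroyed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_surrogates):
        surr_eps = []
        for ep in epochs.epochs:
            if ep.n_samples < 2:
                raise ConfigurationError("epochs must have >= 2 samples to shuffle")
            shifts = rng.integers(1, ep.n_samples, size=ep.n_channels)
            data = np.empty_like(ep.data)
            for c, t in enumerate(shifts):
                data[c] = np.concatenate([ep.data[c, t:], ep.data[c, :t]])
            surr_eps.append(ep.copy_with(data))
        out.append(EpochSet(surr_eps, epochs.epoch_length, epochs.band))
    return out


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class PhiBarEstimate:
    """Sample-unit-averaged, surrogate-corrected integrated information."""

    mean_phi: float
    surrogate_median_mean: float
    phi_bar: float
    n_surrogates: int
    unit_phi: np.ndarray
    unit_surrogate_median: np.ndarray


@dataclass
class ReliabilityCurve:
    """Coefficient of variance of phi_bar vs number of sample units k."""

    k: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    cov: np.ndarray
    n_repeats: int

    def loglog_slope(self) -> float:
        """Slope of log CoV on log k (about -1/2 for independent unit draws)."""
        ok = np.isfinite(self.cov) & (self.cov > 0)
        return float(np.polyfit(np.log(self.k[ok]), np.log(self.cov[ok]), 1)[0])


@dataclass
class RegionalPhiMap:
    """Per-channel regional contribution phi_bar_R(i)."""

    values: np.ndarray
    channel_labels: list[str]
    units_per_channel: int
    seed: int | None

    def as_dict(self) -> dict[str, float]:
        return {l: float(v) for l, v in zip(self.channel_labels, self.values)}


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

class PhiBarModel:
    """Sample-unit estimator of integrated information for an epoched recording.

    The model owns everything that is fixed for a given dataset: the pooled
    lagged moments of the real data and of ``n_surrogates`` shuffle
    surrogates (computed lazily, once).  ``fit`` draws (or accepts) a set of
    sample units and returns a :class:`PhiBarResults`.

    Parameters
    ----------
    epochs : EpochSet
        Band-filtered, epoched recording.
    n, k : int
        Channels per sample unit and number of units (defaults 8 and 600).
    tau : int
        Regression lag in samples (default 1).
    estimator : {"ar", "e"}
        Prediction-error (AR) or Gaussian conditional-covariance form.
    n_surrogates : int
        Shuffle surrogates per dataset for the spurious-phi correction.
    seed : int
        Seed for surrogate generation (unit draws get their own seed in
        ``fit``).
    """

    def __init__(self, epochs: EpochSet, n: int = 8, k: int = 600, tau: int = 1,
                 estimator: str = "ar", n_surrogates: int = 20,
                 normalize_mip: bool = False, ridge: float = RIDGE_DEFAULT,
                 seed: int = 0):
        self.epochs = epochs
        self.n = n
        self.k = k
        self.tau = tau
        self.estimator = estimator
        self.n_surrogates = n_surrogates
        self.normalize_mip = normalize_mip
        self.ridge = ridge
        self.seed = seed
        self._moments: LaggedMoments | None = None
        self._surr_moments: list[LaggedMoments] | None = None

    @property
    def n_channels(self) -> int:
        return self.epochs.n_channels

    @property
    def moments(self) -> LaggedMoments:
        if self._moments is None:
            self._moments = lagged_moments(self.epochs, self.tau)
        return self._moments

    @property
    def surrogate_moments(self) -> list[LaggedMoments]:
        if self._surr_moments is None:
            surr_seed = int(np.random.SeedSequence(self.seed).generate_state(1)[0] % 2**31)
            surrs = surrogate_shuffle(self.epochs, self.n_surrogates, surr_seed)
            self._surr_moments = [lagged_moments(s, self.tau) for s in surrs]
        return self._surr_moments

    def _evaluate_units(self, units: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-unit Phi on real data, surrogate medians, and MIP indices."""
        phi_real, mip = _phi_min(self.moments, units, self.estimator,
                                 self.normalize_mip, self.ridge)
        surr = np.empty((self.n_surrogates, len(units)))
        for j, sm in enumerate(self.surrogate_moments):
            surr[j], _ = _phi_min(sm, units, self.estimator,
                                  self.normalize_mip, self.ridge)
        return phi_real, np.median(surr, axis=0), mip

    def fit(self, seed: int | None = None,
            units: SampleUnitSet | None = None) -> "PhiBarResults":
        """Estimate phi_bar from ``self.k`` random units (or the given set)."""
        if units is None:
            units = draw_sample_units(self.n_channels, self.n, self.k,
                                      seed=self.seed if seed is None else seed)
        phi_real, surr_med, mip = self._evaluate_units(units.units)
        return PhiBarResults(self, units, phi_real, surr_med, mip)

    def reliability_curve(self, k_grid=None, n_repeats: int = 300,
                          seed: int | None = None) -> ReliabilityCurve:
        """CoV of phi_bar over repeated independent unit draws, per k.

        For each k the estimate is repeated ``n_repeats`` times on the same
        data with fresh unit draws; CoV(k) = std/mean of the repeat
        distribution.
        """
        if k_grid is None:
            k_grid = [10, 30, 100, 300, 600]
        k_grid = np.asarray(sorted(k_grid))
        rng = np.random.default_rng(self.seed if seed is None else seed)
        means = np.empty(len(k_grid))
        stds = np.empty(len(k_grid))
        covs = np.empty(len(k_grid))
        for i, k in enumerate(k_grid):
            all_units = draw_sample_units(self.n_channels, self.n,
                                          int(k) * n_repeats, rng=rng).units
            phi_real, surr_med, _ = self._evaluate_units(all_units)
            corrected = (phi_real - surr_med).reshape(n_repeats, int(k))
            estimates = corrected.mean(axis=1)
            means[i] = estimates.mean()
            stds[i] = estimates.std(ddof=1)
            if abs(means[i]) < 1e-12:
                warnings.warn(f"phi_bar mean ~ 0 at k={k}; CoV undefined")
                covs[i] = np.inf
            else:
                covs[i] = stds[i] / abs(means[i])
        return ReliabilityCurve(k=k_grid, mean=means, std=stds, cov=covs,
                                n_repeats=n_repeats)

    def regional(self, units_per_channel: int = 30,
                 seed: int | None = None) -> RegionalPhiMap:
        """Regional contribution map phi_bar_R(i).

        For each channel i, ``units_per_channel`` units constrained to
        contain i (i plus n-1 uniform others) are drawn; the map value is the
        mean corrected Phi over those units.
        """
        c = self.n_channels
        rng = np.random.default_rng(self.seed if seed is None else seed)
        units = np.empty((c * units_per_channel, self.n), dtype=np.int64)
        row = 0
        for i in range(c):
            others = np.delete(np.arange(c), i)
            for _ in range(units_per_channel):
                pick = rng.choice(others, size=self.n - 1, replace=False)
                units[row] = np.sort(np.concatenate(([i], pick)))
                row += 1
        phi_real, surr_med, _ = self._evaluate_units(units)
        corrected = (phi_real - surr_med).reshape(c, units_per_channel)
        return RegionalPhiMap(values=corrected.mean(axis=1),
                              channel_labels=list(self.epochs.channel_labels),
                              units_per_channel=units_per_channel, seed=seed)


class PhiBarResults:
    """Fitted phi_bar estimate with per-unit detail and a text summary."""

    def __init__(self, model: PhiBarModel, units: SampleUnitSet,
                 unit_phi: np.ndarray, unit_surrogate_median: np.ndarray,
                 mip_index: np.ndarray):
        self.model = model
        self.units = units
        self.unit_phi = unit_phi
        self.unit_surrogate_median = unit_surrogate_median
        self.mip_index = mip_index

    @property
    def mean_phi(self) -> float:
        return float(self.unit_phi.mean())

    @property
    def surrogate_median_mean(self) -> float:
        return float(self.unit_surrogate_median.mean())

    @property
    def phi_bar(self) -> float:
        return self.mean_phi - self.surrogate_median_mean

    @property
    def unit_corrected(self) -> np.ndarray:
        return self.unit_phi - self.unit_surrogate_median

    def se_phi_bar(self) -> float:
        """Monte-Carlo standard error of phi_bar over unit draws."""
        return float(self.unit_corrected.std(ddof=1) / np.sqrt(self.units.k))

    def mips(self) -> list[Bipartition]:
        parts = enumerate_bipartitions(self.units.n)
        return [parts[i] for i in self.mip_index]

    def as_estimate(self) -> PhiBarEstimate:
        return PhiBarEstimate(
            mean_phi=self.mean_phi, surrogate_median_mean=self.surrogate_median_mean,
            phi_bar=self.phi_bar, n_surrogates=self.model.n_surrogates,
            unit_phi=self.unit_phi, unit_surrogate_median=self.unit_surrogate_median,
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Integrated information (sample-unit estimator)",
            "=" * 52,
            f"estimator:            phi~{m.estimator.upper()}  (tau = {m.tau} sample(s))",
            f"channels:             {m.n_channels}",
            f"sample units:         k = {self.units.k}, n = {self.units.n} channels/unit",
            f"surrogates:           {m.n_surrogates} (split-and-swap, per-unit median)",
            "-" * 52,
            f"mean unit Phi:        {self.mean_phi: .6f} nats",
            f"surrogate correction: {self.surrogate_median_mean: .6f} nats",
            f"phi_bar:              {self.phi_bar: .6f} nats",
            f"MC s.e. (unit draws): {self.se_phi_bar(): .6f} nats",
            "=" * 52,
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# functional surface
# --------------------------------------------------------------------------

def phi_bar(epochs: EpochSet, unit_set: SampleUnitSet | None = None, tau: int = 1,
            estimator: str = "ar", n_surrogates: int = 20, seed: int = 0,
            n: int = 8, k: int = 600, **kw) -> PhiBarEstimate:
    """One-call phi_bar estimate (see :class:`PhiBarModel`)."""
    model = PhiBarModel(epochs, n=unit_set.n if unit_set else n,
                        k=unit_set.k if unit_set else k, tau=tau,
                        estimator=estimator, n_surrogates=n_surrogates,
                        seed=seed, **kw)
    return model.fit(units=unit_set).as_estimate()


def reliability_curve(epochs: EpochSet, n: int = 8, k_grid=None,
                      n_repeats: int = 300, seed: int = 0, tau: int = 1,
                      estimator: str = "ar", n_surrogates: int = 20) -> ReliabilityCurve:
    """CoV-vs-k reliability protocol on one dataset (see PhiBarModel.reliability_curve)."""
    model = PhiBarModel(epochs, n=n, tau=tau, estimator=estimator,
                        n_surrogates=n_surrogates, seed=seed)
    return model.reliability_curve(k_grid=k_grid, n_repeats=n_repeats, seed=seed)


def regional_phi(epochs: EpochSet, units_per_channel: int = 30, n: int = 8,
                 tau: int = 1, estimator: str = "ar", n_surrogates: int = 20,
                 seed: int = 0) -> RegionalPhiMap:
    """Regional phi_bar_R map (see PhiBarModel.regional)."""
    model = PhiBarModel(epochs, n=n, tau=tau, estimator=estimator,
                        n_surrogates=n_surrogates, seed=seed)
    return model.regional(units_per_channel=units_per_channel, seed=seed)
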