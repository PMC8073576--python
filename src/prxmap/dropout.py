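"""Probabilistic-dropout differential abundance for LFQ intensity matrices.

Missing values in label-free proteomics are informative: low-abundance
proteins drop out of the identification more often.  Rather than imputing,
this module models each cell of the matrix jointly as

* observed with density ``N(y; mu_ic, sigma_i^2) * (1 - Phi((rho_j - y)/zeta_j))``
* missing with probability ``integral N(y; mu_ic, sigma_i^2) * Phi((rho_j - y)/zeta_j) dy
  = Phi((rho_j - mu_ic) / sqrt(zeta_j^2 + sigma_i^2))``

where ``mu_ic`` is protein *i*'s latent log2 mean in condition *c*,
``sigma_i`` a protein-level residual sd shared across conditions, and
``(rho_j, zeta_j)`` the per-sample sigmoidal dropout curve (intensity of
50% dropout and transition width).  The two branches form a properly
normalized joint density over (missingness indicator, value), so maximum
likelihood uses observed values and the informative absence of missing
ones without imputation.

The public surface is statsmodels-like: build a
:class:`ProbabilisticDropoutModel` from an intensity matrix and design,
call :meth:`~ProbabilisticDropoutModel.fit`, and query the returned
:class:`DropoutResults` for contrasts (log2 fold changes with moderated
standard errors, t-based p-values and BH q-values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from scipy.optimize import brentq
from scipy.stats import norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .containers import LOG2, ExperimentDesign, IntensityMatrix

SIGMA_BOUNDS = (0.05, 10.0)
_MIN_PROXY = 20


# ---------------------------------------------------------------------------
# dropout curves


def estimate_dropout_curves(
    matrix: IntensityMatrix,
    design: ExperimentDesign,
    min_proxy: int = _MIN_PROXY,
) -> pd.DataFrame:
    """Estimate the per-sample detection-limit curve (rho_j, zeta_j).

    For sample *j*, the detection-limit proxy set holds the observed
    values in *j* of proteins that are missing in at least one replicate
    of the same (isoform, genotype) condition: values caught right at the
    edge of detectability.  ``rho_j``/``zeta_j`` are its mean and sd.  If
    fewer than ``min_proxy`` proxies exist (e.g. nearly complete data),
    the curve falls back to the 10th percentile of the sample's observed
    values with unit width, and ``fallback`` is flagged.

    Returns a DataFrame indexed by sample id with columns
    ``rho``, ``zeta``, ``fallback``, ``n_proxy``.
    """
    if matrix.scale != LOG2:
        raise ValueError("dropout curves are estimated on log2-scale data")
    vals = matrix.values.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if not obs.any(axis=0).all():
        j = int(np.argmin(obs.any(axis=0)))
        raise ValueError(f"sample {matrix.sample_ids[j]!r} has no observed values")

    labels = design.condition_labels.loc[matrix.sample_ids]
    rows = []
    for j, sid in enumerate(matrix.sample_ids):
        cond_cols = np.flatnonzero((labels == labels.iloc[j]).to_numpy())
        missing_in_cond = (~obs[:, cond_cols]).any(axis=1)
        proxy = vals[obs[:, j] & missing_in_cond, j]
        if len(proxy) >= min_proxy:
            rho = float(proxy.mean())
            zeta = float(proxy.std(ddof=1))
            zeta = max(zeta, 1e-3)
            fallback = False
        else:
            rho = float(np.quantile(vals[obs[:, j], j], 0.10))
            zeta = 1.0
            fallback = True
        rows.append((sid, rho, zeta, fallback, int(len(proxy))))
    return pd.DataFrame(
        rows, columns=["sample_id", "rho", "zeta", "fallback", "n_proxy"]
    ).set_index("sample_id")


def missing_loglik(mu, sigma, rho, zeta):
    """Log probability that a cell is missing under the joint model.

    Closed form of ``log integral N(y; mu, sigma^2) Phi((rho - y)/zeta) dy
    = log Phi((rho - mu) / sqrt(zeta^2 + sigma^2))``.  Accepts scalars or
    broadcastable arrays.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    s = np.sqrt(np.asarray(zeta, dtype=float) ** 2 + sigma**2)
    return norm.logcdf((np.asarray(rho, dtype=float) - np.asarray(mu, dtype=float)) / s)


# ---------------------------------------------------------------------------
# vectorized likelihood machinery


def _phi_ratio(z):
    """phi(z)/Phi(z), numerically stable via log forms (inverse Mills ratio)."""
    return np.exp(_LOG_INV_SQRT_2PI - 0.5 * z * z - special.log_ndtr(z))


_LOG_INV_SQRT_2PI = -0.5 * np.log(2 * np.pi)


class _LikelihoodData:
    """Pre-extracted sufficient statistics and sparse missing-cell indices.

    The observed-data part of the likelihood only needs per-condition
    (count, sum, sum of squares); the missing part is evaluated on the
    flattened list of missing cells and row-summed with bincount, so no
    dense proteins x samples temporaries are built in the inner loops.
    """

    def __init__(self, Y: np.ndarray, groups: np.ndarray, rho: np.ndarray, zeta: np.ndarray):
        self.obs = ~np.isnan(Y)
        self.groups = groups  # condition index per sample
        self.rho = rho
        self.zeta = zeta
        self.n, self.m = Y.shape
        self.n_cond = int(groups.max()) + 1
        Y0 = np.nan_to_num(Y, nan=0.0)
        finite_obs = Y[self.obs]
        vmin = finite_obs.min() if finite_obs.size else rho.min()
        vmax = finite_obs.max() if finite_obs.size else rho.max()
        self.mu_lo = float(min(vmin, rho.min()) - 10.0)
        self.mu_hi = float(max(vmax, rho.max()) + 10.0)
        # parameter-free selection term for observed cells: log(1 - Phi((rho-y)/zeta))
        with np.errstate(invalid="ignore"):
            sel = special.log_ndtr(-(rho[None, :] - Y) / zeta[None, :])
        self.const = np.where(self.obs, sel, 0.0).sum(axis=1)
        self.cond_cols = [np.flatnonzero(groups == c) for c in range(self.n_cond)]

        # observed-part sufficient statistics, per condition
        self.n_obs_per_cond = np.empty((self.n, self.n_cond), dtype=int)
        self.sum_y = np.empty((self.n, self.n_cond))
        self.sum_y2 = np.empty((self.n, self.n_cond))
        for c, cols in enumerate(self.cond_cols):
            Oc = self.obs[:, cols]
            self.n_obs_per_cond[:, c] = Oc.sum(axis=1)
            self.sum_y[:, c] = np.where(Oc, Y0[:, cols], 0.0).sum(axis=1)
            self.sum_y2[:, c] = np.where(Oc, Y0[:, cols] ** 2, 0.0).sum(axis=1)
        self.n_obs_total = self.n_obs_per_cond.sum(axis=1)

        # missing cells, flattened; per-condition views for the mu updates
        miss_row, miss_col = np.nonzero(~self.obs)
        self.miss_row = miss_row
        self.miss_cond = groups[miss_col]
        self.miss_rho = rho[miss_col]
        self.miss_zeta2 = zeta[miss_col] ** 2
        self._miss_by_cond = [
            np.flatnonzero(self.miss_cond == c) for c in range(self.n_cond)
        ]

        # detection-limit anchor for conditions with no observations: the
        # latent mean is unidentified below the dropout curve, so it is
        # pinned one curve-width below the condition's average 50%-dropout
        # intensity (within the bound max rho + zeta)
        self.pinned_mu = np.array(
            [
                (rho[cols] - zeta[cols]).mean() if len(cols) else np.nan
                for cols in self.cond_cols
            ]
        )

    def objective(self, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """Joint log-likelihood per protein; mu (n, C), sigma (n,)."""
        s2 = sigma**2
        ss = (
            self.sum_y2 - 2.0 * mu * self.sum_y + self.n_obs_per_cond * mu**2
        ).sum(axis=1)
        obs_ll = (
            -0.5 * self.n_obs_total * np.log(2 * np.pi * s2) - ss / (2 * s2)
        )
        if len(self.miss_row):
            mu_miss = mu[self.miss_row, self.miss_cond]
            s_miss = np.sqrt(self.miss_zeta2 + s2[self.miss_row])
            ll = special.log_ndtr((self.miss_rho - mu_miss) / s_miss)
            miss_ll = np.bincount(self.miss_row, weights=ll, minlength=self.n)
        else:
            miss_ll = 0.0
        return obs_ll + miss_ll + self.const

    def _newton_mu(self, mu: np.ndarray, sigma: np.ndarray, max_iter: int = 60) -> np.ndarray:
        """Per-condition concave 1-D Newton updates, vectorized over proteins."""
        mu = mu.copy()
        s2 = sigma**2
        for c in range(self.n_cond):
            has_obs = self.n_obs_per_cond[:, c] > 0
            # all-missing condition: the likelihood is one-sided (flat below
            # the dropout curve), so the mean is pinned at the detection limit
            mu[~has_obs, c] = self.pinned_mu[c]
            if not has_obs.any():
                continue
            midx = self._miss_by_cond[c]
            mrow = self.miss_row[midx]
            mrho = self.miss_rho[midx]
            s_miss = np.sqrt(self.miss_zeta2[midx] + s2[mrow])
            n_obs = self.n_obs_per_cond[:, c]
            sum_y = self.sum_y[:, c]
            m = mu[:, c].copy()
            for _ in range(max_iter):
                g = (sum_y - n_obs * m) / s2
                H = -(n_obs / s2).astype(float)
                if len(midx):
                    z = (mrho - m[mrow]) / s_miss
                    ratio = _phi_ratio(z)
                    g -= np.bincount(mrow, weights=ratio / s_miss, minlength=self.n)
                    h = ratio * (z + ratio)
                    H -= np.bincount(mrow, weights=h / s_miss**2, minlength=self.n)
                step = g / np.minimum(H, -1e-10)
                step = np.where(has_obs, step, 0.0)
                m = np.clip(m - step, self.mu_lo, self.mu_hi)
                if np.max(np.abs(step)) < 1e-10:
                    break
            mu[has_obs, c] = m[has_obs]
        return mu

    def _optimize_sigma(self, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """Per-protein sigma via coarse log grid then golden-section refine."""
        lo, hi = SIGMA_BOUNDS
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), 25))
        scores = np.stack(
            [self.objective(mu, np.full(self.n, g)) for g in grid], axis=1
        )
        best = np.argmax(scores, axis=1)
        a = np.log(grid[np.maximum(best - 1, 0)])
        b = np.log(grid[np.minimum(best + 1, len(grid) - 1)])
        invphi = (np.sqrt(5.0) - 1) / 2
        for _ in range(40):
            x1 = b - invphi * (b - a)
            x2 = a + invphi * (b - a)
            f1 = self.objective(mu, np.exp(x1))
            f2 = self.objective(mu, np.exp(x2))
            take_left = f1 > f2
            b = np.where(take_left, x2, b)
            a = np.where(take_left, a, x1)
        out = np.exp((a + b) / 2)
        base = self.objective(mu, sigma)
        new = self.objective(mu, out)
        return np.where(new >= base, out, sigma)


# ---------------------------------------------------------------------------
# variance moderation


@dataclass
class ModerationPrior:
    """Empirical-Bayes scaled-inverse-chi-squared prior on protein variances."""

    d0: float
    s0_sq: float

    def posterior_var(self, sigma_sq, df):
        sigma_sq = np.asarray(sigma_sq, dtype=float)
        df = np.asarray(df, dtype=float)
        if np.isinf(self.d0):
            return np.full_like(sigma_sq, self.s0_sq)
        finite = np.isfinite(df)
        safe_df = np.where(finite, df, 1.0)
        post = (self.d0 * self.s0_sq + safe_df * sigma_sq) / (self.d0 + safe_df)
        post = np.where(finite, post, sigma_sq)  # exact variances stay as-is
        return np.where(df > 0, post, self.s0_sq)


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    f = lambda x: float(special.polygamma(1, x) - y)
    lo, hi = 1e-8, 1e8
    if f(lo) < 0:
        return lo
    if f(hi) > 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-10)


def moderate_variances(sigma_sq, df) -> tuple[ModerationPrior, np.ndarray]:
    """Fit the variance prior by matching log-scale moments.

    Under ``s_i^2 ~ s0^2 * d0/chi^2_{d0}`` observed through ``df_i`` residual
    degrees of freedom, ``e_i = log s_i^2 - digamma(df_i/2) + log(df_i/2)``
    has mean ``log s0^2 + digamma(d0/2) - log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond the sampling term ``trigamma(df_i/2)``; the
    prior is recovered by inverting the trigamma.  ``df`` may be ``inf``
    for exactly-known variances.  Returns the prior and per-protein
    posterior (moderated) variances.
    """
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), sigma_sq.shape).copy()
    usable = np.isfinite(sigma_sq) & (sigma_sq > 0) & (df > 0)
    if usable.sum() < 2:
        s0 = float(sigma_sq[usable][0]) if usable.any() else 1.0
        prior = ModerationPrior(d0=np.inf, s0_sq=s0)
        return prior, prior.posterior_var(sigma_sq, df)

    s2 = sigma_sq[usable]
    d = df[usable]
    if np.ptp(s2) < 1e-12:  # degenerate input: literally identical variances
        prior = ModerationPrior(d0=np.inf, s0_sq=float(s2[0]))
        return prior, prior.posterior_var(sigma_sq, df)
    finite = np.isfinite(d)
    safe_d = np.where(finite, d, 2.0)
    corr_mean = np.where(finite, special.digamma(safe_d / 2) - np.log(safe_d / 2), 0.0)
    corr_var = np.where(finite, special.polygamma(1, safe_d / 2), 0.0)
    e = np.log(s2) - corr_mean
    e_var = float(np.var(e, ddof=1) - corr_var.mean())
    if e_var <= 1e-12:  # variances essentially identical given their noise
        d0 = np.inf
        s0_sq = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2)))
    prior = ModerationPrior(d0=d0, s0_sq=s0_sq)
    return prior, prior.posterior_var(sigma_sq, df)


# ---------------------------------------------------------------------------
# model / results


class ProbabilisticDropoutModel:
    """Dropout-aware differential abundance model for one intensity matrix.

    Parameters
    ----------
    matrix
        log2-scale, normalized intensity matrix.
    design
        Experiment design covering the matrix's samples.
    groups
        Optional sample -> condition labels overriding the default
        (isoform, genotype) conditions; used e.g. to pool all baits of one
        isoform against all others.
    curves
        Pre-estimated dropout curves (DataFrame from
        :func:`estimate_dropout_curves`); estimated on the fly if absent.
    """

    def __init__(
        self,
        matrix: IntensityMatrix,
        design: ExperimentDesign,
        groups: pd.Series | None = None,
        curves: pd.DataFrame | None = None,
    ):
        if matrix.scale != LOG2:
            raise ValueError("model expects log2-scale data")
        missing_samples = set(matrix.sample_ids) - set(design.sample_ids)
        if missing_samples:
            raise ValueError(f"design does not cover samples {sorted(missing_samples)}")
        self.matrix = matrix
        self.design = design.subset(matrix.sample_ids)
        if groups is None:
            groups = self.design.condition_labels
        self.groups = groups.loc[matrix.sample_ids]
        if curves is None:
            curves = estimate_dropout_curves(matrix, self.design)
        self.curves = curves.loc[matrix.sample_ids]
        self.condition_names = list(dict.fromkeys(self.groups))

    def fit(self, moderate: bool = True, maxiter: int = 200, tol: float = 1e-8) -> "DropoutResults":
        """Coordinate-ascent maximum likelihood, then variance moderation.

        Alternates concave Newton updates of the condition means with a
        golden-section update of each protein's sigma until the objective
        improves by less than ``tol``.
        """
        cond_index = {c: k for k, c in enumerate(self.condition_names)}
        groups = np.array([cond_index[g] for g in self.groups])
        Y = self.matrix.values.to_numpy(dtype=float)
        data = _LikelihoodData(
            Y, groups, self.curves["rho"].to_numpy(), self.curves["zeta"].to_numpy()
        )

        # deterministic init: observed condition means; all-missing
        # conditions start (and stay) at the detection-limit anchor
        mu = np.empty((data.n, data.n_cond))
        for c, cols in enumerate(data.cond_cols):
            counts = data.obs[:, cols].sum(axis=1)
            sums = np.where(data.obs[:, cols], Y[:, cols], 0.0).sum(axis=1)
            mu[:, c] = np.where(
                counts > 0, sums / np.maximum(counts, 1), data.pinned_mu[c]
            )
        resid = Y - mu[:, groups]
        ss = np.where(data.obs, resid, 0.0) ** 2
        df_init = np.maximum(data.obs.sum(axis=1) - (data.n_obs_per_cond > 0).sum(axis=1), 1)
        sigma = np.sqrt(np.maximum(ss.sum(axis=1) / df_init, 1e-12))
        sigma = np.clip(np.where(np.isfinite(sigma), sigma, 1.0), *SIGMA_BOUNDS)

        obj = data.objective(mu, sigma)
        converged = np.zeros(data.n, dtype=bool)
        for _ in range(maxiter):
            mu = data._newton_mu(mu, sigma)
            sigma = data._optimize_sigma(mu, sigma)
            new_obj = data.objective(mu, sigma)
            gain = new_obj - obj
            obj = new_obj
            converged = gain < tol
            if converged.all():
                break

        n_obs_total = data.obs.sum(axis=1)
        n_active = (data.n_obs_per_cond > 0).sum(axis=1)
        df_resid = np.maximum(n_obs_total - n_active, 0).astype(float)

        sigma_sq_ml = sigma**2
        with np.errstate(divide="ignore", invalid="ignore"):
            # de-bias the ML variance toward a residual-df scale before pooling
            s2_for_prior = np.where(
                df_resid > 0, sigma_sq_ml * n_obs_total / np.maximum(df_resid, 1), np.nan
            )
        if moderate and np.isfinite(s2_for_prior).sum() >= 2:
            prior, sigma_sq_mod = moderate_variances(s2_for_prior, df_resid)
            sigma_sq_mod = np.where(np.isfinite(sigma_sq_mod), sigma_sq_mod, prior.s0_sq)
        else:
            prior = ModerationPrior(d0=0.0, s0_sq=float(np.nanmean(sigma_sq_ml)))
            sigma_sq_mod = np.where(df_resid > 0, s2_for_prior, np.nan)
            sigma_sq_mod = np.where(np.isfinite(sigma_sq_mod), sigma_sq_mod, sigma_sq_ml)

        return DropoutResults(
            model=self,
            data=data,
            mu=pd.DataFrame(mu, index=self.matrix.protein_ids, columns=self.condition_names),
            sigma=pd.Series(sigma, index=self.matrix.protein_ids, name="sigma"),
            sigma_sq_mod=pd.Series(sigma_sq_mod, index=self.matrix.protein_ids),
            prior=prior,
            df_resid=pd.Series(df_resid, index=self.matrix.protein_ids),
            objective=pd.Series(obj, index=self.matrix.protein_ids),
            converged=pd.Series(converged, index=self.matrix.protein_ids),
        )


@dataclass
class DropoutResults:
    """Fitted condition means, variances and contrast machinery."""

    model: ProbabilisticDropoutModel
    data: _LikelihoodData
    mu: pd.DataFrame
    sigma: pd.Series
    sigma_sq_mod: pd.Series
    prior: ModerationPrior
    df_resid: pd.Series
    objective: pd.Series
    converged: pd.Series

    @property
    def mu_bounds(self) -> tuple[float, float]:
        return (self.data.mu_lo, self.data.mu_hi)

    @property
    def n_obs(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.data.n_obs_per_cond,
            index=self.mu.index,
            columns=self.mu.columns,
        )

    def _condition_information(self, cond: str) -> np.ndarray:
        """Information for mu_c at the moderated variance.

        Conditions with observations use the observed Fisher information
        of the joint likelihood (Gaussian term per observed cell plus the
        probit-curvature term per missing cell).  A condition that is
        entirely missing has a one-sided, asymptotically flat likelihood;
        its mean is pinned at the detection limit and the missing values
        are treated as distributed around that limit with the dropout
        curve's spread, giving information n_miss / (zeta^2 + sigma^2).
        """
        c = list(self.mu.columns).index(cond)
        cols = self.data.cond_cols[c]
        s2 = self.sigma_sq_mod.to_numpy()
        info = self.data.n_obs_per_cond[:, c] / s2
        if len(cols):
            s_miss_sq = self.data.zeta[cols][None, :] ** 2 + s2[:, None]
            s_miss = np.sqrt(s_miss_sq)
            z = (self.data.rho[cols][None, :] - self.mu.to_numpy()[:, c][:, None]) / s_miss
            ratio = _phi_ratio(z)
            h = ratio * (z + ratio)
            miss = ~self.data.obs[:, cols]
            info = info + np.where(miss, h / s_miss_sq, 0.0).sum(axis=1)
            all_missing = self.data.n_obs_per_cond[:, c] == 0
            detection_limit_info = len(cols) / (
                np.mean(self.data.zeta[cols] ** 2) + s2
            )
            info = np.where(all_missing, detection_limit_info, info)
        return np.maximum(info, 1e-12)

    def contrast(self, cond_a: str, cond_b: str) -> pd.DataFrame:
        """Log2 fold change cond_a - cond_b with moderated Wald inference.

        Returns a DataFrame with columns ``protein_id, delta, se, p, q,
        n_obs_a, n_obs_b``; ``q`` is Benjamini-Hochberg adjusted within
        this contrast.
        """
        for cond in (cond_a, cond_b):
            if cond not in self.mu.columns:
                raise ValueError(f"condition {cond!r} not in model")
        if cond_a == cond_b:
            raise ValueError("cannot contrast a condition with itself")
        delta = self.mu[cond_a] - self.mu[cond_b]
        info_a = self._condition_information(cond_a)
        info_b = self._condition_information(cond_b)
        se = np.sqrt(1.0 / info_a + 1.0 / info_b)

        ia = list(self.mu.columns).index(cond_a)
        ib = list(self.mu.columns).index(cond_b)
        n_obs_a = self.data.n_obs_per_cond[:, ia]
        n_obs_b = self.data.n_obs_per_cond[:, ib]
        df_pair = np.maximum(n_obs_a + n_obs_b - 2.0, 1.0)
        d0 = self.prior.d0 if np.isfinite(self.prior.d0) else 1e6
        df_t = df_pair + d0

        tstat = delta.to_numpy() / se
        p = 2.0 * t_dist.sf(np.abs(tstat), df_t)
        p = np.clip(p, 0.0, 1.0)
        q = multipletests(p, method="fdr_bh")[1]
        return pd.DataFrame(
            {
                "protein_id": self.mu.index,
                "delta": delta.to_numpy(),
                "se": se,
                "p": p,
                "q": q,
                "n_obs_a": n_obs_a,
                "n_obs_b": n_obs_b,
            }
        ).set_index("protein_id")

    def summary(self) -> str:
        lines = [
            "Probabilistic dropout model",
            "===========================",
            f"proteins:          {self.mu.shape[0]}",
            f"samples:           {self.data.m}",
            f"conditions:        {', '.join(self.mu.columns)}",
            f"missing cells:     {(~self.data.obs).mean():.1%}",
            f"converged:         {int(self.converged.sum())}/{len(self.converged)}",
            f"variance prior:    d0={self.prior.d0:.3g}, s0^2={self.prior.s0_sq:.4g}",
            f"median sigma:      {float(self.sigma.median()):.4g}",
            "dropout curves (per sample):",
        ]
        for sid, row in self.model.curves.iterrows():
            tag = " [fallback]" if row["fallback"] else ""
            lines.append(f"  {sid}: rho={row['rho']:.2f}, zeta={row['zeta']:.2f}{tag}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# convenience wrappers


def fit_protein_model(
    y: pd.Series,
    design: ExperimentDesign,
    curves: pd.DataFrame,
    groups: pd.Series | None = None,
) -> DropoutResults:
    """Fit the dropout model for a single protein row (one-row matrix)."""
    mat = IntensityMatrix(y.to_frame().T, scale=LOG2)
    model = ProbabilisticDropoutModel(mat, design, groups=groups, curves=curves)
    return model.fit(moderate=False)


def test_contrast(results: DropoutResults, cond_a: str, cond_b: str) -> pd.DataFrame:
    """Functional alias for :meth:`DropoutResults.contrast`."""
    return results.contrast(cond_a, cond_b)
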