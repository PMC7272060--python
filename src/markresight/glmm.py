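"""Bayesian binomial mixed model of marked-detection probability.

The probability P that a resighted turtle carries the paint mark is
modelled per survey row (period i, day j, diel slot k) as

    marked_seen ~ Binomial(total_seen, P)
    logit(P) = alpha + beta[method] + b_i + b_ij + b_ijk + eps

with a method fixed effect (reference level SO, so the betas are contrasts
against the historical surface-observer platform), nested Gaussian random
intercepts for survey period, day-within-period and diel-within-day, and an
observation-level Gaussian residual ``eps`` carrying binomial
overdispersion (a binomial GLMM has no free residual variance, so the
residual error enters as a per-row random intercept).

Under equal detectability of marked and unmarked turtles, P should not
differ between methods; a positive SO-versus-UAV contrast is the signature
of marked-detection bias in the surface-observer counts.

Priors are vague: Gaussian(0, 10^2) on the fixed effects and half-Cauchy
(scale 5) on every random-effect standard deviation.  Inference is by a
Metropolis-within-Gibbs sampler written for this model:

* fixed effects and latent intercepts are updated by random-walk
  Metropolis, vectorised within each level (groups of one level touch
  disjoint rows, so their accept/reject decisions are independent), with
  step sizes adapted during burn-in toward 30-45% acceptance;
* the variance parameters are updated by conjugate Gibbs draws via the
  inverse-gamma parameter expansion of the half-Cauchy prior
  (sigma^2 | a ~ InvGamma((n+1)/2, sum(b^2)/2 + 1/a),
  a | sigma^2 ~ InvGamma(1, 1/A^2 + 1/sigma^2));
* each iteration ends with exact-Gibbs *translation sweeps* along the
  hierarchy (intercept vs period effects, period vs day, day vs diel, diel
  vs residual): a shift delta is moved from a parent to its children,
  leaving every linear predictor — and hence the likelihood — unchanged,
  with delta drawn from its Gaussian full conditional under the priors.
  These sweeps decorrelate the intercept from the random effects, whose
  sums are tightly pinned by large counts, and are essential for the
  intercept to mix.

The sampler is deterministic given its seed.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import METHODS, Dataset, EstimationError

_SIGMA_COMPONENTS = ("period", "day", "diel", "resid")


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval: shortest window of sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty draws")
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat over an (m_chains, n_draws) array."""
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2:
        return float("nan")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = np.var(means, ddof=1)
    v_hat = (n - 1) / n * W + B_over_n
    if W == 0:
        return 1.0
    return float(np.sqrt(v_hat / W))


def _binom_loglik(eta: np.ndarray, m: np.ndarray, n: np.ndarray) -> np.ndarray:
    # log Binomial(m | n, expit(eta)) up to the binomial coefficient
    return m * eta - n * np.logaddexp(0.0, eta)


@dataclass
class _Level:
    """One random-effect level: group index per row, current values, step size."""

    name: str
    idx: np.ndarray  # row -> group
    n_groups: int
    values: np.ndarray = field(init=False)
    step: float = 0.3
    fixed_sigma: Optional[float] = None
    sig2: float = 0.1
    aux: float = 1.0
    accepts: float = 0.0
    attempts: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.zeros(self.n_groups)


class DetectionGLMM:
    """Binomial mixed model of the per-survey marked fraction.

    Parameters
    ----------
    data : Dataset or DataFrame
        Survey rows; a DataFrame needs columns ``period_id, day, diel,
        method, marked_seen, total_seen`` (or ``unmarked_seen``).
    reference : str
        Fixed-effect reference method (default ``"SO"``); betas are
        contrasts against it.
    prior_sd_fixed : float
        SD of the Gaussian prior on intercept and method contrasts.
    prior_scale_sigma : float
        Scale of the half-Cauchy prior on random-effect SDs.
    sigma_fixed : mapping, optional
        Fix named variance components (``period``, ``day``, ``diel``,
        ``resid``) at a constant SD; fixing at 0 removes the component
        (used e.g. to reduce the model to a fixed-effects logistic
        regression for cross-checks).
    use_likelihood : bool
        If False the sampler targets the prior only — a standard
        sampler-correctness diagnostic.
    """

    def __init__(
        self,
        data: Union[Dataset, pd.DataFrame],
        *,
        reference: str = "SO",
        prior_sd_fixed: float = 10.0,
        prior_scale_sigma: float = 5.0,
        sigma_fixed: Optional[Mapping[str, float]] = None,
        use_likelihood: bool = True,
    ) -> None:
        df = data.to_frame() if isinstance(data, Dataset) else data.copy()
        if "total_seen" not in df.columns:
            df["total_seen"] = df["marked_seen"] + df["unmarked_seen"]
        if (df["total_seen"] < 1).any():
            bad = df.index[df["total_seen"] < 1][0]
            raise EstimationError(
                f"survey row {bad} has total_seen < 1; every row must have at "
                "least one sighting"
            )
        if (df["marked_seen"] > df["total_seen"]).any():
            bad = df.index[df["marked_seen"] > df["total_seen"]][0]
            raise EstimationError(f"survey row {bad} has marked_seen > total_seen")
        methods = [m for m in METHODS if m in set(df["method"])]
        if len(methods) < 2:
            raise EstimationError("need surveys from at least two methods")
        self.reference = reference if reference in methods else methods[0]
        self.methods = methods
        self.contrast_methods = [m for m in methods if m != self.reference]
        self.prior_sd_fixed = float(prior_sd_fixed)
        self.prior_scale_sigma = float(prior_scale_sigma)
        self.sigma_fixed = dict(sigma_fixed or {})
        self.use_likelihood = bool(use_likelihood)

        self._m = df["marked_seen"].to_numpy(dtype=float)
        self._n = df["total_seen"].to_numpy(dtype=float)
        self._method_rows = {
            m: (df["method"] == m).to_numpy() for m in self.contrast_methods
        }
        per_key = df["period_id"].astype(str)
        day_key = per_key + "|" + df["day"].astype(str)
        diel_key = day_key + "|" + df["diel"].astype(str)
        per_codes = pd.factorize(per_key)[0]
        day_codes = pd.factorize(day_key)[0]
        diel_codes = pd.factorize(diel_key)[0]
        obs_codes = np.arange(len(df))
        self._level_index = {
            "period": (per_codes, per_codes.max() + 1),
            "day": (day_codes, day_codes.max() + 1),
            "diel": (diel_codes, diel_codes.max() + 1),
            "resid": (obs_codes, len(df)),
        }
        self.nobs = len(df)
        self.frame = df
        self._pmap_cache: dict[tuple[str, str], np.ndarray] = {}

    def _parent_map(self, child_name: str, parent_name: str) -> np.ndarray:
        """child group -> enclosing parent group (levels are nested)."""
        key = (child_name, parent_name)
        if key not in self._pmap_cache:
            cidx, cn = self._level_index[child_name]
            pidx, _ = self._level_index[parent_name]
            pmap = np.zeros(cn, dtype=int)
            pmap[cidx] = pidx
            self._pmap_cache[key] = pmap
        return self._pmap_cache[key]

    # ------------------------------------------------------------------
    def _init_state(self) -> tuple[float, dict[str, float], list[_Level]]:
        p0 = float(np.clip(self._m.sum() / self._n.sum(), 1e-4, 1 - 1e-4))
        alpha = float(logit(p0))
        beta = {m: 0.0 for m in self.contrast_methods}
        levels = []
        for name in _SIGMA_COMPONENTS:
            idx, g = self._level_index[name]
            lev = _Level(name, idx, g)
            if name in self.sigma_fixed:
                lev.fixed_sigma = float(self.sigma_fixed[name])
                lev.sig2 = lev.fixed_sigma**2
            levels.append(lev)
        return alpha, beta, levels

    def _loglik(self, eta: np.ndarray) -> np.ndarray:
        if not self.use_likelihood:
            return np.zeros_like(eta)
        return _binom_loglik(eta, self._m, self._n)

    def fit(
        self,
        n_iter: int = 5_000,
        n_burn: int = 1_000,
        n_chains: int = 1,
        thin: int = 1,
        seed: int = 0,
    ) -> "DetectionGLMMResults":
        """Run the sampler and return a results object with posterior draws.

        ``n_iter`` counts post-burn-in iterations per chain; ``n_burn``
        adaptation iterations are run and discarded first.
        """
        all_draws = []
        for chain in range(n_chains):
            rng = np.random.default_rng([int(seed), chain])
            all_draws.append(self._run_chain(rng, chain, n_iter, n_burn, thin))
        draws = pd.concat(all_draws, ignore_index=True)
        if len(draws) < 200:
            _warnings.warn(
                f"only {len(draws)} retained posterior draws; summaries will be "
                "noisy (increase n_iter or reduce thin)",
                stacklevel=2,
            )
        return DetectionGLMMResults(
            model=self,
            draws=draws,
            n_chains=n_chains,
            n_iter=n_iter,
            n_burn=n_burn,
            thin=thin,
            seed=seed,
        )

    # ------------------------------------------------------------------
    def _run_chain(self, rng, chain, n_iter, n_burn, thin) -> pd.DataFrame:
        alpha, beta, levels = self._init_state()
        step_alpha, step_beta = 0.1, {m: 0.1 for m in beta}
        acc = {"alpha": [0.0, 0.0], **{f"beta_{m}": [0.0, 0.0] for m in beta}}

        eta = np.full(self.nobs, alpha)
        for m, rows in self._method_rows.items():
            eta[rows] += beta[m]
        for lev in levels:
            eta += lev.values[lev.idx]
        cur_ll = self._loglik(eta)
        if not np.all(np.isfinite(cur_ll)):
            bad = int(np.flatnonzero(~np.isfinite(cur_ll))[0])
            raise EstimationError(
                f"non-finite likelihood at survey row {bad}: "
                f"{self.frame.iloc[bad].to_dict()}"
            )

        prior_var_fixed = self.prior_sd_fixed**2
        A2 = self.prior_scale_sigma**2
        records = []
        total = n_burn + n_iter
        for it in range(total):
            adapting = it < n_burn
            # --- fixed effects ------------------------------------------------
            prop = alpha + rng.normal(0.0, step_alpha)
            d_eta = prop - alpha
            new_ll = self._loglik(eta + d_eta)
            logr = (
                new_ll.sum()
                - cur_ll.sum()
                - (prop**2 - alpha**2) / (2 * prior_var_fixed)
            )
            acc["alpha"][1] += 1
            if np.log(rng.random()) < logr:
                alpha = prop
                eta = eta + d_eta
                cur_ll = new_ll
                acc["alpha"][0] += 1
            for m in self.contrast_methods:
                rows = self._method_rows[m]
                prop = beta[m] + rng.normal(0.0, step_beta[m])
                d = prop - beta[m]
                if self.use_likelihood:
                    new_ll_rows = _binom_loglik(
                        eta[rows] + d, self._m[rows], self._n[rows]
                    )
                else:
                    new_ll_rows = np.zeros(int(rows.sum()))
                logr = (
                    (np.sum(new_ll_rows) - cur_ll[rows].sum())
                    - (prop**2 - beta[m] ** 2) / (2 * prior_var_fixed)
                )
                acc[f"beta_{m}"][1] += 1
                if np.log(rng.random()) < logr:
                    beta[m] = prop
                    eta[rows] += d
                    if self.use_likelihood:
                        cur_ll[rows] = new_ll_rows
                    acc[f"beta_{m}"][0] += 1
            # --- random-effect values (vectorised per level) ------------------
            for lev in levels:
                if lev.fixed_sigma == 0.0:
                    continue
                delta = rng.normal(0.0, lev.step, size=lev.n_groups)
                eta_new = eta + delta[lev.idx]
                new_ll = self._loglik(eta_new)
                d_ll = np.bincount(
                    lev.idx, weights=new_ll - cur_ll, minlength=lev.n_groups
                )
                v_new = lev.values + delta
                d_prior = -(v_new**2 - lev.values**2) / (2 * lev.sig2)
                accept = np.log(rng.random(lev.n_groups)) < d_ll + d_prior
                if accept.any():
                    lev.values = np.where(accept, v_new, lev.values)
                    row_acc = accept[lev.idx]
                    eta = np.where(row_acc, eta_new, eta)
                    cur_ll = np.where(row_acc, new_ll, cur_ll)
                lev.accepts += accept.mean()
                lev.attempts += 1
                # --- variance parameter (Gibbs, half-Cauchy via expansion) ----
                if lev.fixed_sigma is None:
                    shape = (lev.n_groups + 1) / 2
                    rate = 0.5 * np.sum(lev.values**2) + 1.0 / lev.aux
                    lev.sig2 = rate / rng.gamma(shape)
                    lev.aux = (1.0 / A2 + 1.0 / lev.sig2) / rng.gamma(1.0)
            # --- translation sweeps (likelihood-invariant exact Gibbs) --------
            active = [lev for lev in levels if lev.fixed_sigma != 0.0]
            if active:
                lev0 = active[0]
                prec = 1.0 / prior_var_fixed + lev0.n_groups / lev0.sig2
                mean = (
                    -alpha / prior_var_fixed + lev0.values.sum() / lev0.sig2
                ) / prec
                delta = rng.normal(mean, 1.0 / np.sqrt(prec))
                alpha += delta
                lev0.values = lev0.values - delta
            for parent, child in zip(active, active[1:]):
                pmap = self._parent_map(child.name, parent.name)
                n_child = np.bincount(pmap, minlength=parent.n_groups)
                child_sum = np.bincount(
                    pmap, weights=child.values, minlength=parent.n_groups
                )
                prec = 1.0 / parent.sig2 + n_child / child.sig2
                mean = (-parent.values / parent.sig2 + child_sum / child.sig2) / prec
                delta = rng.normal(mean, 1.0 / np.sqrt(prec))
                parent.values = parent.values + delta
                child.values = child.values - delta[pmap]
            # --- step-size adaptation during burn-in --------------------------
            if adapting and (it + 1) % 50 == 0:
                for key, scale_ref in [("alpha", None)] + [
                    (f"beta_{m}", m) for m in self.contrast_methods
                ]:
                    a, t = acc[key]
                    rate = a / t if t else 0.0
                    fac = 0.8 if rate < 0.30 else (1.25 if rate > 0.45 else 1.0)
                    if key == "alpha":
                        step_alpha = float(np.clip(step_alpha * fac, 1e-3, 50.0))
                    else:
                        step_beta[scale_ref] = float(
                            np.clip(step_beta[scale_ref] * fac, 1e-3, 50.0)
                        )
                    acc[key] = [0.0, 0.0]
                for lev in levels:
                    if lev.attempts:
                        rate = lev.accepts / lev.attempts
                        fac = 0.8 if rate < 0.30 else (1.25 if rate > 0.45 else 1.0)
                        lev.step = float(np.clip(lev.step * fac, 1e-3, 50.0))
                        lev.accepts = lev.attempts = 0.0
            # --- record -------------------------------------------------------
            if it >= n_burn and (it - n_burn) % thin == 0:
                rec = {"chain": chain, "iteration": it - n_burn, "alpha": alpha}
                for m in self.contrast_methods:
                    rec[f"beta_{m}"] = beta[m]
                for lev in levels:
                    rec[f"sigma_{lev.name}"] = float(np.sqrt(lev.sig2))
                records.append(rec)
        return pd.DataFrame(records)


def fit_detection_model(
    data: Union[Dataset, pd.DataFrame],
    n_iter: int = 5_000,
    n_burn: int = 1_000,
    n_chains: int = 1,
    seed: int = 0,
    **model_kwargs,
) -> "DetectionGLMMResults":
    """Convenience wrapper: build a :class:`DetectionGLMM` and fit it."""
    return DetectionGLMM(data, **model_kwargs).fit(
        n_iter=n_iter, n_burn=n_burn, n_chains=n_chains, seed=seed
    )


@dataclass
class DetectionGLMMResults:
    """Posterior draws and summaries for a fitted :class:`DetectionGLMM`."""

    model: DetectionGLMM
    draws: pd.DataFrame
    n_chains: int
    n_iter: int
    n_burn: int
    thin: int = 1
    seed: int = 0

    @property
    def param_names(self) -> list[str]:
        return [c for c in self.draws.columns if c not in ("chain", "iteration")]

    @property
    def params(self) -> pd.Series:
        """Posterior means."""
        return self.draws[self.param_names].mean()

    def hpd(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.draws[name].to_numpy(), prob)

    def rhat(self) -> pd.Series:
        """Gelman-Rubin statistic per parameter (NaN with a single chain)."""
        out = {}
        for name in self.param_names:
            chains = [
                g[name].to_numpy() for _, g in self.draws.groupby("chain", sort=True)
            ]
            n = min(len(c) for c in chains)
            out[name] = gelman_rubin(np.vstack([c[:n] for c in chains]))
        return pd.Series(out)

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        """Posterior mean, SD, HPD bounds and R-hat per parameter."""
        rows = []
        rh = self.rhat()
        for name in self.param_names:
            x = self.draws[name].to_numpy()
            lo, hi = hpd_interval(x, prob)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)),
                    "hpd_low": lo,
                    "hpd_high": hi,
                    "rhat": rh[name],
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        head = (
            f"DetectionGLMM results: {self.model.nobs} survey rows, "
            f"reference method {self.model.reference}, "
            f"{self.n_chains} chain(s) x {self.n_iter} iterations "
            f"(burn-in {self.n_burn})\n"
        )
        return head + self.summary().to_string(index=False, float_format="%.4f")

    # ------------------------------------------------------------------
    def variance_partition(
        self, prob: float = 0.95, include_residual: bool = False
    ) -> pd.DataFrame:
        """Share of random-effect variance per component, with HPD intervals.

        Per draw, ``share_c = sigma_c^2 / sum_c sigma_c^2`` over the nested
        components (period, day, diel); the observation-level residual is
        excluded unless ``include_residual``.  Draws in which every
        component is zero get uniform shares (with a warning).
        """
        if len(self.draws) < 200:
            _warnings.warn("fewer than 200 draws; partition will be noisy")
        comps = ["period", "day", "diel"] + (["resid"] if include_residual else [])
        sig2 = np.column_stack(
            [self.draws[f"sigma_{c}"].to_numpy() ** 2 for c in comps]
        )
        total = sig2.sum(axis=1)
        zero = total == 0
        if zero.any():
            _warnings.warn(
                f"{int(zero.sum())} draw(s) have all variance components zero; "
                "their shares are set to uniform"
            )
            sig2[zero] = 1.0
            total[zero] = len(comps)
        shares = sig2 / total[:, None]
        rows = []
        for j, c in enumerate(comps):
            lo, hi = hpd_interval(shares[:, j], prob)
            rows.append(
                {
                    "component": c,
                    "share_mean": float(shares[:, j].mean()),
                    "hpd_low": lo,
                    "hpd_high": hi,
                }
            )
        return pd.DataFrame(rows)

    def marked_proportions(
        self, prob: float = 0.95, marginal: bool = False, n_quad: int = 21
    ) -> pd.DataFrame:
        """Posterior marked fraction per method, with a central interval.

        By default the fixed-effects (conditional) scale is reported:
        ``expit(alpha + beta_method)`` per draw.  With ``marginal=True``
        the random effects are integrated out by Gauss-Hermite quadrature
        over a Gaussian with the draw's total random-effect variance.
        """
        a = self.draws["alpha"].to_numpy()
        if marginal:
            sig2 = sum(
                self.draws[f"sigma_{c}"].to_numpy() ** 2 for c in _SIGMA_COMPONENTS
            )
            nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
            weights = weights / np.sqrt(np.pi)
            nodes = np.sqrt(2.0) * nodes
        lohi = (1 - prob) / 2
        rows = []
        for m in self.model.methods:
            etad = a.copy()
            if m != self.model.reference:
                etad = etad + self.draws[f"beta_{m}"].to_numpy()
            if marginal:
                p = (
                    expit(etad[:, None] + np.sqrt(sig2)[:, None] * nodes[None, :])
                    * weights[None, :]
                ).sum(axis=1)
            else:
                p = expit(etad)
            rows.append(
                {
                    "method": m,
                    "mean": float(np.mean(p)),
                    "ci_low": float(np.quantile(p, lohi)),
                    "ci_high": float(np.quantile(p, 1 - lohi)),
                }
            )
        return pd.DataFrame(rows)
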