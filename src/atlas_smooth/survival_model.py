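"""Period-method relative-survival (excess hazard) model with a Leroux field.

Cell deaths are Poisson, d_itk ~ Poisson(mu_itk), with
mu_itk = d*_itk + y_itk exp(alpha_t + sum_k beta_k x_k + S_i):
the expected other-cause deaths enter as a fixed offset and the excess
hazard is log-linear in follow-up year, stratum and area.  Priors:
alpha_t ~ N(0, 1000), beta_k ~ N(0, 1000), rho ~ Uniform(0, 1) and, as the
production default, a half-Normal prior on the spatial variance itself,
sigma2 ~ N(0, 5) truncated to (0, inf).  The key output is the excess
hazard ratio exp(S_i).

The variance-prior family is a sensitivity hook: half-Normal on the
variance (default), half-Normal on the standard deviation, or
inverse-gamma (which is conjugate and updated by Gibbs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mcmc import McmcConfig, PosteriorDraws, StepAdapter, leroux_quadform_delta, reflect_unit
from .spatial_structure import AreaGraph
from .standardisation import SurvivalTable

__all__ = ["SurvivalParams", "survival_mean", "excess_mean", "fit_survival", "ehr_draws"]

LP_CLAMP = 30.0
N_FOLLOWUP = 5


@dataclass
class SurvivalParams:
    alpha: np.ndarray  # five follow-up-year intercepts
    beta: np.ndarray   # one coefficient per stratum indicator
    S: np.ndarray
    sigma2: float = 1.0
    rho: float = 0.5

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.alpha.shape != (N_FOLLOWUP,):
            raise ValueError("five follow-up-year intercepts required")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def excess_mean(y, dstar, lp):
    """mu = d* + y exp(lp); equals d* when y = 0 and exceeds it whenever y > 0."""
    y = np.asarray(y, dtype=float)
    dstar = np.asarray(dstar, dtype=float)
    return dstar + y * np.exp(lp)


def survival_mean(row, params: SurvivalParams):
    """Expected total deaths for one table cell under ``params``.

    ``row`` is any mapping with person_time, expected_deaths, followup_year
    (1-based), stratum index ``k`` and area index ``i``.
    """
    lp = (
        params.alpha[int(row["followup_year"]) - 1]
        + (params.beta[int(row["k"])] if len(params.beta) else 0.0)
        + params.S[int(row["i"])]
    )
    return float(excess_mean(row["person_time"], row["expected_deaths"], lp))


@dataclass
class VariancePrior:
    """Sensitivity hook for the spatial-variance hyperprior."""

    family: str = "half_normal"     # half_normal | inverse_gamma
    variance: float = 5.0           # half-normal scale parameter (a variance)
    on: str = "variance"            # variance | sd (software conventions differ)
    shape: float = 1.0              # inverse-gamma shape
    scale: float = 0.01             # inverse-gamma scale

    def __post_init__(self) -> None:
        if self.family not in ("half_normal", "inverse_gamma"):
            raise ValueError(f"unknown variance prior family {self.family!r}")
        if self.on not in ("variance", "sd"):
            raise ValueError("half-normal prior applies to 'variance' or 'sd'")

    def logpdf(self, sigma2: float) -> float:
        if self.family != "half_normal":
            raise RuntimeError("logpdf only used for the half-normal family")
        if self.on == "variance":
            return -(sigma2**2) / (2.0 * self.variance)
        # half-normal on sigma, expressed as a density in sigma2
        return -sigma2 / (2.0 * self.variance) - 0.5 * np.log(sigma2)


def fit_survival(
    table: SurvivalTable,
    graph: AreaGraph,
    config: McmcConfig | None = None,
    fix: dict | None = None,
    variance_prior: VariancePrior | None = None,
) -> PosteriorDraws:
    """Posterior draws for the excess-hazard model.

    Stratum coefficients are included whenever the table has two or more
    strata; a single-stratum table reduces to the intercept-only layout.
    ``fix`` pins parameters (``S``, ``sigma2``, ``rho``) for oracle checks.
    """
    config = config or McmcConfig()
    fix = fix or {}
    vp = variance_prior or VariancePrior()
    if set(table.area_ids) - set(graph.area_ids):
        raise ValueError("graph must cover all areas in the table")
    i_idx, k_idx, t_idx, d, y, dstar = table.design(area_ids=graph.area_ids)
    K = len(table.strata)
    for k, lab in enumerate(table.strata):
        if y[k_idx == k].sum() <= 0:
            raise ValueError(f"stratum {lab!r} has zero total person-time; beta is inestimable")

    # cells with no person-time carry no information (and no deaths)
    live = y > 0
    i_idx, k_idx, t_idx = i_idx[live], k_idx[live], t_idx[live]
    d, y, dstar = d[live], y[live], dstar[live]

    n = graph.n_areas
    use_beta = K >= 2
    rng = np.random.default_rng(config.seed)
    Wc = graph.csr()
    deg = graph.neighbour_counts
    lam = np.linalg.eigvalsh(np.diag(deg) - graph.W)
    classes = graph.colour_classes()
    class_rows = [np.flatnonzero(np.isin(i_idx, cls)) for cls in classes]
    class_pos = []
    for cls, rows in zip(classes, class_rows):
        pos_of = {a: p for p, a in enumerate(cls)}
        class_pos.append(np.array([pos_of[a] for a in i_idx[rows]], dtype=int))

    alpha = np.full(N_FOLLOWUP, np.log(max(d.sum() - dstar.sum(), 0.5) / y.sum()))
    beta = np.zeros(K)
    S = np.full(n, float(fix["S"])) if "S" in fix else np.zeros(n)
    sigma2 = float(fix.get("sigma2", 0.5))
    rho = float(fix.get("rho", 0.5))

    a_adapt = StepAdapter(np.full(N_FOLLOWUP, config.step_scalar), config.target_accept, config.adapt_interval)
    k_adapt = StepAdapter(np.full(K, config.step_scalar), config.target_accept, config.adapt_interval)
    s_adapt = StepAdapter(np.full(n, config.step_s), config.target_accept, config.adapt_interval)
    v_adapt = StepAdapter(config.step_sigma2, config.target_accept, config.adapt_interval)
    r_adapt = StepAdapter(config.step_rho, config.target_accept, config.adapt_interval)

    retained = config.retained
    out = {
        "alpha": np.empty((retained, N_FOLLOWUP)),
        "beta": np.empty((retained, K)),
        "S": np.empty((retained, n)),
        "sigma2": np.empty(retained),
        "rho": np.empty(retained),
    }
    prior_prec = 1.0 / 1000.0
    update_S = "S" not in fix
    update_s2 = "sigma2" not in fix
    update_rho = "rho" not in fix
    kept = 0
    clip_hits = 0

    def loglik_rows(lp, rows=None):
        if rows is None:
            mu = dstar + y * np.exp(np.clip(lp, -LP_CLAMP, LP_CLAMP))
            return d * np.log(mu) - mu
        mu = dstar[rows] + y[rows] * np.exp(np.clip(lp, -LP_CLAMP, LP_CLAMP))
        return d[rows] * np.log(mu) - mu

    for it in range(config.burn_in + config.iterations):
        adapting = it < config.burn_in
        Q0_diag = rho * deg + (1.0 - rho)
        lp = alpha[t_idx] + (beta[k_idx] if use_beta else 0.0) + S[i_idx]
        base = loglik_rows(lp)

        # alpha_t: each row belongs to one follow-up year, so the five
        # components are conditionally independent and move as a block
        z = a_adapt.step * rng.standard_normal(N_FOLLOWUP)
        dlik = np.bincount(t_idx, loglik_rows(lp + z[t_idx]) - base, minlength=N_FOLLOWUP)
        logacc = dlik - prior_prec * ((alpha + z) ** 2 - alpha**2) / 2.0
        acc = np.log(rng.random(N_FOLLOWUP)) < logacc
        alpha = np.where(acc, alpha + z, alpha)
        (a_adapt.record if adapting else a_adapt.record_frozen)(acc)
        lp = alpha[t_idx] + (beta[k_idx] if use_beta else 0.0) + S[i_idx]
        base = loglik_rows(lp)

        if use_beta:
            z = k_adapt.step * rng.standard_normal(K)
            dlik = np.bincount(k_idx, loglik_rows(lp + z[k_idx]) - base, minlength=K)
            logacc = dlik - prior_prec * ((beta + z) ** 2 - beta**2) / 2.0
            acc = np.log(rng.random(K)) < logacc
            beta = np.where(acc, beta + z, beta)
            (k_adapt.record if adapting else k_adapt.record_frozen)(acc)
            lp = alpha[t_idx] + beta[k_idx] + S[i_idx]
            base = loglik_rows(lp)

            # translation Gibbs move between the alpha and beta blocks
            prec_c = (N_FOLLOWUP + K) * prior_prec
            mean_c = prior_prec * (beta.sum() - alpha.sum()) / prec_c
            c = mean_c + rng.standard_normal() / np.sqrt(prec_c)
            alpha += c
            beta -= c

        if update_S:
            accepted = np.zeros(n)
            for cls, rows, pos in zip(classes, class_rows, class_pos):
                WS = Wc @ S
                z = s_adapt.step[cls] * rng.standard_normal(cls.size)
                dlik = np.bincount(
                    pos, loglik_rows(lp[rows] + z[pos], rows) - base[rows], minlength=cls.size
                )
                dquad = leroux_quadform_delta(Q0_diag, WS, rho, S, S[cls] + z, cls)
                logacc = dlik - dquad / (2.0 * sigma2)
                acc = np.log(rng.random(cls.size)) < logacc
                S[cls] = np.where(acc, S[cls] + z, S[cls])
                accepted[cls] = acc
                dz = np.where(acc, z, 0.0)
                lp[rows] += dz[pos]
                base[rows] = loglik_rows(lp[rows], rows)
            (s_adapt.record if adapting else s_adapt.record_frozen)(accepted)

            if config.centre_moves:
                # exact Gibbs translation (S - c, alpha_t + c for all t)
                prec_c = (1.0 - rho) * n / sigma2 + N_FOLLOWUP * prior_prec
                mean_c = ((1.0 - rho) * S.sum() / sigma2 - prior_prec * alpha.sum()) / prec_c
                c = mean_c + rng.standard_normal() / np.sqrt(prec_c)
                S -= c
                alpha += c

        s_dw = float(deg @ S**2 - S @ (Wc @ S))
        s_ss = float(S @ S)

        if update_s2:
            quad = rho * s_dw + (1.0 - rho) * s_ss
            if vp.family == "inverse_gamma":
                sigma2 = (vp.scale + quad / 2.0) / rng.gamma(vp.shape + n / 2.0)
            else:
                prop = float(sigma2 * np.exp(v_adapt.step * rng.standard_normal()))
                logacc = (
                    vp.logpdf(prop) - vp.logpdf(sigma2)
                    - (n / 2.0) * np.log(prop / sigma2)
                    - quad / 2.0 * (1.0 / prop - 1.0 / sigma2)
                    + np.log(prop / sigma2)  # Jacobian of the log-scale walk
                )
                acc = np.log(rng.random()) < logacc
                if acc:
                    sigma2 = prop
                (v_adapt.record if adapting else v_adapt.record_frozen)(float(acc))

        if update_rho:
            prop = reflect_unit(rho + r_adapt.step * rng.standard_normal())
            with np.errstate(divide="ignore"):
                dlogdet = 0.5 * float(
                    np.sum(np.log(prop * lam + 1.0 - prop))
                    - np.sum(np.log(rho * lam + 1.0 - rho))
                )
            logacc = dlogdet - (prop - rho) * (s_dw - s_ss) / (2.0 * sigma2)
            acc = np.isfinite(logacc) and np.log(rng.random()) < logacc
            if acc:
                rho = float(prop)
            (r_adapt.record if adapting else r_adapt.record_frozen)(float(acc))

        if it % 128 == 0:
            lp_max = float(np.max(np.abs(lp)))
            if lp_max > LP_CLAMP:
                clip_hits += 1
            if not np.isfinite(lp_max) or not np.isfinite(sigma2):
                raise RuntimeError(f"non-finite sampler state at iteration {it}")

        if it >= config.burn_in and (it - config.burn_in + 1) % config.thin == 0:
            out["alpha"][kept] = alpha
            out["beta"][kept] = beta
            out["S"][kept] = S
            out["sigma2"][kept] = sigma2
            out["rho"][kept] = rho
            kept += 1

    if clip_hits:
        warnings.warn(
            f"linear predictor exceeded |lp| <= {LP_CLAMP} in {clip_hits} iterations",
            RuntimeWarning,
        )
    return PosteriorDraws(
        out,
        {
            "alpha": a_adapt.rate,
            "beta": k_adapt.rate if use_beta else float("nan"),
            "S": s_adapt.rate,
            "sigma2": v_adapt.rate if vp.family == "half_normal" else 1.0,
            "rho": r_adapt.rate,
        },
        config,
        area_ids=graph.area_ids,
    )


def ehr_draws(draws: PosteriorDraws) -> np.ndarray:
    """Per-area excess hazard ratio draw matrix exp(S_i)."""
    return np.exp(draws.get("S"))
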