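"""Twin-pair heritability by maximum-likelihood variance decomposition.

The model is the additive-genetic / unique-environment (AE) polygenic
model.  For phenotype vector y with fixed-effect design X,

    y ~ N(X beta, Omega),   Omega = 2 Phi sigma_g^2 + I sigma_e^2,

where 2 Phi holds the expected additive-genetic covariance fraction
between relatives: 1.0 on the diagonal and for MZ co-twins, 0.5 for
DZ/full-sibling co-twins, 0 between families.  Narrow-sense
heritability is h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

Omega is block-diagonal by family, so the Gaussian log-likelihood
factorizes over families; for twin pairs each block is 2 x 2 and the
whole likelihood reduces to a handful of sufficient statistics per
zygosity group, making a single evaluation O(p^2).  beta is profiled
out by GLS at each variance-parameter value, and (sigma_g^2,
sigma_e^2) are maximized numerically under sigma_g^2 >= 0,
sigma_e^2 > 0 with multiple starts (a Falconer-informed start, an
even split, and a near-null start).

Because sigma_g^2 is tested on the boundary of its parameter space,
the likelihood-ratio statistic for h^2 > 0 is referred to a 50:50
mixture of chi^2_0 and chi^2_1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import ConvergenceError, InsufficientDataError, Pedigree

_TWO_PHI = {"MZ": 1.0, "DZ": 0.5}


@dataclass
class KinshipStructure:
    """Block-diagonal expected-genetic-covariance multipliers (2 Phi).

    ``families`` maps family_id -> (member individual_ids, 2 Phi block);
    ``individual_ids`` fixes the phenotype ordering (family-contiguous).
    Twin pairs give 2 x 2 blocks; the container representation admits
    larger sibships, though the fitter supports pairs only.
    """

    individual_ids: list[str]
    families: dict[str, tuple[list[str], np.ndarray]] = field(repr=False)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def dense_two_phi(self) -> np.ndarray:
        """Full n x n 2*Phi matrix (zero between families)."""
        n = self.n_individuals
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        out = np.zeros((n, n))
        for ids, block in self.families.values():
            idx = [pos[i] for i in ids]
            out[np.ix_(idx, idx)] = block
        return out


def build_kinship(pedigree: Pedigree) -> KinshipStructure:
    """Expected additive-genetic covariance structure from a twin pedigree.

    MZ co-twins share all additive variance (off-diagonal 1.0); DZ
    co-twins, like full siblings, share half (0.5); diagonal 1.0.
    """
    families: dict[str, tuple[list[str], np.ndarray]] = {}
    order: list[str] = []
    for fam_id, grp in pedigree.families():
        ids = grp["individual_id"].tolist()
        zyg = grp["zygosity"].iloc[0]
        m = _TWO_PHI[zyg]
        k = len(ids)
        block = np.full((k, k), m)
        np.fill_diagonal(block, 1.0)
        families[fam_id] = (ids, block)
        order.extend(ids)
    return KinshipStructure(individual_ids=order, families=families)


def twin_design_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Default fixed-effect design: intercept, age, sex, age x sex.

    Sex is coded as an indicator (F = 0, M = 1); the interaction is
    age times that indicator.
    """
    df = pedigree.table
    sex = (df["sex"] == "M").astype(float)
    design = pd.DataFrame(
        {
            "const": 1.0,
            "age": df["age"].to_numpy(float),
            "sex": sex.to_numpy(float),
            "age_x_sex": df["age"].to_numpy(float) * sex.to_numpy(float),
        },
        index=pd.Index(df["individual_id"], name="individual_id"),
    )
    return design


def falconer_h2(
    phenotype: np.ndarray | pd.Series,
    pedigree: Pedigree,
    exog: np.ndarray | pd.DataFrame | None = None,
) -> float:
    """Falconer's heritability estimate 2 (r_MZ - r_DZ).

    Twin correlations are double-entry Pearson correlations per
    zygosity group, optionally on residuals from an OLS covariate
    adjustment.  A quick moment-based counterpart to the likelihood
    fit; also used to seed the optimizer.
    """
    y = _align_phenotype(phenotype, pedigree)
    if exog is not None:
        X = np.asarray(
            exog.loc[pedigree.individual_ids] if isinstance(exog, pd.DataFrame) else exog,
            dtype=float,
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta
    pos = {iid: i for i, iid in enumerate(pedigree.individual_ids)}
    corrs = {}
    for zyg in ("MZ", "DZ"):
        firsts, seconds = [], []
        for _, grp in pedigree.families():
            if grp["zygosity"].iloc[0] != zyg:
                continue
            i, j = (pos[x] for x in grp["individual_id"])
            firsts.append(y[i])
            seconds.append(y[j])
        if len(firsts) < 2:
            raise ValueError(f"need at least 2 {zyg} pairs for a twin correlation")
        a = np.concatenate([firsts, seconds])
        b = np.concatenate([seconds, firsts])
        corrs[zyg] = float(np.corrcoef(a, b)[0, 1])
    return 2.0 * (corrs["MZ"] - corrs["DZ"])


def _align_phenotype(phenotype, pedigree: Pedigree) -> np.ndarray:
    if isinstance(phenotype, pd.Series):
        y = phenotype.loc[pedigree.individual_ids].to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if len(y) != pedigree.n_individuals:
            raise ValueError("phenotype length does not match pedigree")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")
    return y


class PolygenicAE:
    """AE variance-components model for twin-pair phenotypes.

    Parameters
    ----------
    endog : array-like
        Phenotype, ordered as ``kinship.individual_ids`` (a pandas
        Series indexed by individual id is aligned automatically).
    exog : array-like
        Fixed-effect design matrix, same ordering; must be full rank.
    kinship : KinshipStructure
        Output of :func:`build_kinship`.

    Use :meth:`from_pedigree` to assemble endog/exog/kinship from a
    pedigree and a volume Series with the standard covariates
    (intercept, age, sex, age x sex).
    """

    def __init__(self, endog, exog, kinship: KinshipStructure,
                 exog_names: Sequence[str] | None = None):
        self.kinship = kinship
        n = kinship.n_individuals
        if isinstance(endog, pd.Series):
            endog = endog.loc[kinship.individual_ids]
        if isinstance(exog, pd.DataFrame):
            if exog_names is None:
                exog_names = list(exog.columns)
            exog = exog.loc[kinship.individual_ids]
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != n or y.shape[0] != n:
            raise ValueError("endog/exog length must match the kinship ordering")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
            raise ValueError("endog and exog must be finite")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("exog must have full column rank")
        if np.var(y) <= 0:
            raise ValueError("phenotype has zero variance")
        self.endog = y
        self.exog = X
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(X.shape[1])
        ]
        self.nobs = n
        self._prepare_groups()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_pedigree(
        cls,
        phenotype: pd.Series | np.ndarray,
        pedigree: Pedigree,
        covariates: pd.DataFrame | None = None,
    ) -> "PolygenicAE":
        """Build the model from a pedigree and a phenotype vector.

        ``covariates`` defaults to :func:`twin_design_matrix` (intercept,
        age, sex indicator, age x sex).
        """
        kin = build_kinship(pedigree)
        y = _align_phenotype(phenotype, pedigree)
        X = covariates if covariates is not None else twin_design_matrix(pedigree)
        return cls(
            pd.Series(y, index=pedigree.individual_ids), X, kin,
            exog_names=list(X.columns) if isinstance(X, pd.DataFrame) else None,
        )

    def _prepare_groups(self) -> None:
        """Sufficient statistics per zygosity multiplier group.

        For twin pairs every family block is [[v, c], [c, v]] with
        c = m * sigma_g^2, m in {1.0, 0.5}, so the log-likelihood needs
        only pair cross-products accumulated per multiplier value.
        """
        pos = {iid: i for i, iid in enumerate(self.kinship.individual_ids)}
        pairs_by_m: dict[float, list[tuple[int, int]]] = {}
        for ids, block in self.kinship.families.values():
            if len(ids) != 2:
                raise NotImplementedError(
                    "the fitter supports twin-pair families only"
                )
            m = float(block[0, 1])
            pairs_by_m.setdefault(m, []).append((pos[ids[0]], pos[ids[1]]))
        y, X = self.endog, self.exog
        self._groups = []
        for m, idx in pairs_by_m.items():
            i1 = np.array([a for a, _ in idx])
            i2 = np.array([b for _, b in idx])
            X1, X2 = X[i1], X[i2]
            y1, y2 = y[i1], y[i2]
            self._groups.append(
                dict(
                    m=m,
                    n_pairs=len(idx),
                    SXX=X1.T @ X1 + X2.T @ X2,
                    SXC=X1.T @ X2 + X2.T @ X1,
                    SXy=X1.T @ y1 + X2.T @ y2,
                    SXyc=X1.T @ y2 + X2.T @ y1,
                    Syy=float(y1 @ y1 + y2 @ y2),
                    Syc=float(y1 @ y2),
                )
            )

    # -- likelihood -----------------------------------------------------------

    def profile_loglike(self, sigma_g2: float, sigma_e2: float) -> float:
        """Log-likelihood at (sigma_g2, sigma_e2) with beta profiled out
        by GLS."""
        ll, _ = self._loglike_beta(sigma_g2, sigma_e2)
        return ll

    def _loglike_beta(self, sg2: float, se2: float):
        if sg2 < 0 or se2 <= 0:
            return -np.inf, None
        v = sg2 + se2
        p = self.exog.shape[1]
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdet = 0.0
        for g in self._groups:
            c = g["m"] * sg2
            det = v * v - c * c
            if det <= 0:
                return -np.inf, None
            a = v / det
            b = -c / det
            XtWX += a * g["SXX"] + b * g["SXC"]
            XtWy += a * g["SXy"] + b * g["SXyc"]
            ytWy += a * g["Syy"] + 2.0 * b * g["Syc"]
            logdet += g["n_pairs"] * np.log(det)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return -np.inf, None
        quad = ytWy - beta @ XtWy
        ll = -0.5 * (self.nobs * np.log(2.0 * np.pi) + logdet + quad)
        return float(ll), beta

    def loglike_dense(self, sigma_g2: float, sigma_e2: float) -> float:
        """Dense-matrix evaluation of the same profile likelihood.

        Builds the full n x n covariance and solves it directly; an
        O(n^3) cross-check of the blockwise path, useful only at small n.
        """
        two_phi = self.kinship.dense_two_phi()
        omega = sigma_g2 * two_phi + sigma_e2 * np.eye(self.nobs)
        W = np.linalg.inv(omega)
        X, y = self.exog, self.endog
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(omega)
        if sign <= 0:
            return -np.inf
        return float(
            -0.5 * (self.nobs * np.log(2.0 * np.pi) + logdet + r @ W @ r)
        )

    # -- fitting --------------------------------------------------------------

    def _fit_null(self):
        """Closed-form ML fit with sigma_g2 constrained to zero
        (ordinary regression with ML residual variance)."""
        X, y = self.exog, self.endog
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se2 = float(resid @ resid / self.nobs)
        ll = -0.5 * self.nobs * (np.log(2.0 * np.pi * se2) + 1.0)
        return beta, se2, ll

    def fit(self, constrain_g_to_zero: bool = False,
            maxiter: int = 500) -> "PolygenicAEResults":
        """Maximize the likelihood over (sigma_g2 >= 0, sigma_e2 > 0).

        Runs L-BFGS-B from three starts (Falconer-informed, even split,
        near-null) and keeps the best; raises
        :class:`ConvergenceError` if every start fails.
        """
        if self.kinship.n_families < 20:
            raise InsufficientDataError(
                f"variance decomposition needs >= 20 families, "
                f"got {self.kinship.n_families}"
            )
        beta0, s2_tot, ll_null = self._fit_null()
        if constrain_g_to_zero:
            return PolygenicAEResults(
                model=self, sigma_g2=0.0, sigma_e2=s2_tot,
                beta=np.asarray(beta0), loglik=ll_null, loglik_null=ll_null,
                constrained=True,
            )

        # Falconer start from double-entry twin correlations of OLS residuals
        try:
            h2_falc = falconer_h2(
                pd.Series(self.endog, index=self.kinship.individual_ids),
                _pedigree_from_kinship(self.kinship),
                exog=self.exog,
            )
        except Exception:
            h2_falc = 0.3
        h2_falc = float(np.clip(h2_falc, 0.02, 0.95))
        # optimize variance components as fractions of the OLS residual
        # variance so the parameters are O(1) regardless of the
        # phenotype's units (finite-difference gradients need this)
        starts = [
            (h2_falc, 1 - h2_falc),
            (0.5, 0.5),
            (0.02, 0.98),
        ]
        floor = 1e-10

        def nll(theta):
            return -self._loglike_beta(theta[0] * s2_tot, theta[1] * s2_tot)[0]

        best = None
        for sg0, se0 in starts:
            res = optimize.minimize(
                nll, x0=[max(sg0, 0.0), max(se0, floor)],
                method="L-BFGS-B",
                bounds=[(0.0, None), (floor, None)],
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
            )
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun - 0.0:
                best = res
        if best is None:
            raise ConvergenceError(
                "likelihood optimisation failed from all starts "
                f"(n={self.nobs}, starts={starts})"
            )
        sg2, se2 = float(best.x[0] * s2_tot), float(best.x[1] * s2_tot)
        ll, beta = self._loglike_beta(sg2, se2)
        if ll < ll_null - 1e-6 * (1 + abs(ll_null)):
            # the null is nested, so this signals an optimiser failure
            raise ConvergenceError(
                f"full-model likelihood ({ll:.6f}) below null ({ll_null:.6f})"
            )
        return PolygenicAEResults(
            model=self, sigma_g2=sg2, sigma_e2=se2, beta=np.asarray(beta),
            loglik=float(ll), loglik_null=float(ll_null), constrained=False,
        )


def _pedigree_from_kinship(kin: KinshipStructure) -> Pedigree:
    """Minimal pedigree reconstruction (for the Falconer seed only):
    multiplier 1.0 -> MZ, 0.5 -> DZ; ages/sexes are placeholders."""
    rows = []
    for fam, (ids, block) in kin.families.items():
        zyg = "MZ" if float(block[0, 1]) == 1.0 else "DZ"
        for iid in ids:
            rows.append((iid, fam, zyg, "F", 0.0))
    return Pedigree(
        pd.DataFrame(rows, columns=["individual_id", "family_id",
                                    "zygosity", "sex", "age"])
    )


@dataclass
class PolygenicAEResults:
    """Fitted AE model: variance components, heritability and tests."""

    model: PolygenicAE
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    loglik: float
    loglik_null: float
    constrained: bool = False
    _h2_se: float | None = field(default=None, repr=False)

    @property
    def sigma_p2(self) -> float:
        """Total phenotypic variance sigma_g^2 + sigma_e^2."""
        return self.sigma_g2 + self.sigma_e2

    @property
    def h2(self) -> float:
        """Narrow-sense heritability sigma_g^2 / sigma_p^2."""
        return self.sigma_g2 / self.sigma_p2

    @property
    def llf(self) -> float:
        return self.loglik

    @property
    def lrt_stat(self) -> float:
        return max(2.0 * (self.loglik - self.loglik_null), 0.0)

    @property
    def p_value(self) -> float:
        """Boundary-mixture LRT p-value for h^2 > 0."""
        return lrt_pvalue(self.loglik, self.loglik_null)

    @property
    def h2_se(self) -> float:
        """Delta-method standard error of h^2.

        Inverts the numerically differentiated observed information of
        (sigma_g2, sigma_e2) from the profile likelihood and propagates
        through h^2 = sigma_g^2/(sigma_g^2 + sigma_e^2).
        """
        if self._h2_se is None:
            self._h2_se = self._compute_h2_se()
        return self._h2_se

    def _compute_h2_se(self) -> float:
        sg2, se2 = self.sigma_g2, self.sigma_e2
        scale = self.sigma_p2
        h = np.array([max(1e-5 * scale, 1e-10), max(1e-5 * scale, 1e-10)])

        def nll(theta):
            # reflect at the sigma_g2 >= 0 boundary so differences stay valid
            ll = self.model.profile_loglike(abs(theta[0]), theta[1])
            return -ll

        x0 = np.array([sg2, se2])
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                fpp = nll(x0 + ei + ej)
                fpm = nll(x0 + ei - ej)
                fmp = nll(x0 - ei + ej)
                fmm = nll(x0 - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            return float("nan")
        grad = np.array([se2, -sg2]) / (scale * scale)
        var = float(grad @ cov @ grad)
        return float(np.sqrt(var)) if var > 0 else float("nan")

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "AE polygenic model (ML variance decomposition)",
            "=" * 54,
            f"n individuals     {self.model.nobs:>10d}",
            f"n families        {self.model.kinship.n_families:>10d}",
            f"log-likelihood    {self.loglik:>14.4f}",
            f"null log-lik      {self.loglik_null:>14.4f}",
            f"sigma_g^2         {self.sigma_g2:>14.4f}",
            f"sigma_e^2         {self.sigma_e2:>14.4f}",
            f"h^2               {self.h2:>14.4f}",
            f"SE(h^2)           {self.h2_se:>14.4f}",
            f"LRT statistic     {self.lrt_stat:>14.4f}",
            f"p-value           {self.p_value:>14.3e}",
            "-" * 54,
            "fixed effects (GLS at the ML variance estimates):",
        ]
        for name, b in zip(self.model.exog_names, self.beta):
            lines.append(f"  {name:<14s} {b:>14.6f}")
        return "\n".join(lines)


def lrt_pvalue(loglik_full: float, loglik_null: float,
               tol: float = 1e-6) -> float:
    """Likelihood-ratio p-value for a variance component tested on the
    boundary of its parameter space.

    The statistic is Lambda = 2 (loglik_full - loglik_null); under the
    null, Lambda follows a 50:50 mixture of a point mass at zero
    (chi^2_0) and chi^2_1, so p = 0.5 * P(chi^2_1 >= Lambda) for
    Lambda > 0 and p = 0.5 at Lambda = 0.
    """
    lam = 2.0 * (loglik_full - loglik_null)
    if lam < -tol * (1.0 + abs(loglik_null)):
        raise ValueError(
            f"null fit better than full (Lambda={lam:.3g}): optimiser failure"
        )
    lam = max(lam, 0.0)
    if lam == 0.0:
        return 0.5
    return float(0.5 * stats.chi2.sf(lam, df=1))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance level alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return alpha / m


def heritability_table(
    volumes: pd.DataFrame,
    pedigree: Pedigree,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region heritability report.

    Parameters
    ----------
    volumes : DataFrame
        Subjects x regions, indexed by individual_id, covering the
        pedigree members.
    pedigree : Pedigree
    covariates : DataFrame, optional
        Fixed-effect design (defaults to intercept, age, sex,
        age x sex from the pedigree).
    alpha : float
        Family-wise level; each region is flagged significant at
        alpha / n_regions.

    Returns
    -------
    DataFrame with columns h2, se, p, significant, sorted by ascending
    h2.  A region whose fit fails yields a NaN row (with the error in
    the ``error`` column) without aborting the others.
    """
    regions = list(volumes.columns)
    thresh = bonferroni_threshold(alpha, len(regions))
    rows = []
    for region in regions:
        try:
            model = PolygenicAE.from_pedigree(
                volumes[region], pedigree, covariates=covariates
            )
            res = model.fit()
            rows.append(
                dict(region=region, h2=res.h2, se=res.h2_se, p=res.p_value,
                     significant=res.p_value <= thresh, error="")
            )
        except Exception as exc:  # isolate per-region failures
            rows.append(
                dict(region=region, h2=np.nan, se=np.nan, p=np.nan,
                     significant=False, error=str(exc))
            )
    out = pd.DataFrame(rows).set_index("region")
    out.attrs["alpha"] = alpha
    out.attrs["threshold"] = thresh
    return out.sort_values("h2", ascending=True)
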