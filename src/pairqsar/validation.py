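"""OLS model fitting and the QSAR validation battery.

Internal validation: leave-one-out and leave-many-out cross-validated
determination coefficients (Q²_LOO via the hat-matrix deletion
identity, Q²_LMO over random deletion groups), PRESS, RMSE/MAE, and
Lin's concordance correlation coefficient.  External validation:
R²_ext, Q²_F1/F2/F3, CCC_ex, Roy's r²m metrics and the
Golbraikh-Tropsha criteria.  Chance correlation is probed by
Y-randomization; descriptor redundancy by the QUIK rule (Todeschini's
multivariate K correlation index); and the applicability domain by the
Williams plot (leverage vs standardized residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SingularDesignError, UndefinedStatisticError


# ---------------------------------------------------------------------------
# fitting


@dataclass
class MLRModel:
    """An ordinary-least-squares model with its training-fit statistics."""

    descriptor_names: list
    intercept: float
    coefficients: np.ndarray
    intercept_se: float
    coefficient_se: np.ndarray
    r2: float
    r2_adj: float
    f_stat: float
    rmse_tr: float
    mae_tr: float
    rss_tr: float
    ccc_tr: float
    s: float  # standard error of estimate, n - p - 1 denominator
    n_train: int
    y_train_mean: float
    tss_tr: float
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    def equation(self, response: str = "pEC50", digits: int = 3) -> str:
        """Human-readable model equation with ± standard errors."""
        terms = [f"{self.intercept:.{digits}f} (±{self.intercept_se:.{digits}f})"]
        for name, b, se in zip(
            self.descriptor_names, self.coefficients, self.coefficient_se
        ):
            sign = "+" if b >= 0 else "-"
            terms.append(
                f"{sign} {abs(b):.{digits}f} (±{se:.{digits}f}) {name}"
            )
        return f"{response} = " + " ".join(terms)


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def fit_ols(X, y, descriptor_names=None) -> MLRModel:
    """Fit y = b0 + Xb by ordinary least squares.

    Requires n > p + 1 and a full-column-rank design; a rank-deficient
    design raises :class:`SingularDesignError` naming the collinear
    columns.  A constant response yields R² = 0, F = 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if descriptor_names is None:
        descriptor_names = [f"x{j}" for j in range(p)]
    if n <= p + 1:
        raise SingularDesignError(
            columns=[f"n={n} too small for p={p} descriptors"]
        )
    D = _design(X)
    if np.linalg.matrix_rank(D) < p + 1:
        bad = _collinear_columns(X, descriptor_names)
        raise SingularDesignError(columns=bad)

    res = sm.OLS(y, D).fit()
    resid = y - res.fittedvalues
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = tss <= 1e-12 * n * (1.0 + float(np.abs(y).max()) ** 2)
    if degenerate:
        r2, r2_adj, f_stat = 0.0, 0.0, 0.0
    else:
        r2 = 1.0 - rss / tss
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        f_stat = float(res.fvalue)
    return MLRModel(
        descriptor_names=list(descriptor_names),
        intercept=float(res.params[0]),
        coefficients=np.asarray(res.params[1:], dtype=float),
        intercept_se=float(res.bse[0]),
        coefficient_se=np.asarray(res.bse[1:], dtype=float),
        r2=r2,
        r2_adj=r2_adj,
        f_stat=f_stat,
        rmse_tr=float(np.sqrt(rss / n)),
        mae_tr=float(np.abs(resid).mean()),
        rss_tr=rss,
        ccc_tr=ccc(y, np.asarray(res.fittedvalues)) if not degenerate else 0.0,
        s=float(np.sqrt(rss / (n - p - 1))),
        n_train=n,
        y_train_mean=float(y.mean()),
        tss_tr=tss,
        residuals=resid,
        fitted=np.asarray(res.fittedvalues),
    )


def _collinear_columns(X, names):
    """Identify a minimal set of columns involved in the rank deficiency."""
    bad = []
    kept = []
    for j in range(X.shape[1]):
        trial = np.column_stack([np.ones(len(X))] + [X[:, k] for k in kept + [j]])
        if np.linalg.matrix_rank(trial) == len(kept) + 2:
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


# ---------------------------------------------------------------------------
# concordance


def ccc(a, b) -> float:
    """Lin's concordance correlation coefficient (n-denominator moments)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise UndefinedStatisticError("CCC needs two equal-length vectors, n >= 2")
    va = a.var()
    vb = b.var()
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    denom = va + vb + (a.mean() - b.mean()) ** 2
    if denom <= 1e-300:
        raise UndefinedStatisticError("CCC undefined: zero total denominator")
    return float(2.0 * cov / denom)


# ---------------------------------------------------------------------------
# internal validation


def hat_diagonal(X: np.ndarray) -> np.ndarray:
    """Diagonal of H = D (DᵀD)⁻¹ Dᵀ for the intercept-augmented design."""
    D = _design(X)
    Q, _ = np.linalg.qr(D)
    return (Q**2).sum(axis=1)


def q2_loo(X, y) -> dict:
    """Leave-one-out cross-validation via the hat-matrix deletion identity.

    The deletion residual is e_i / (1 - h_i); PRESS is their sum of
    squares and Q²_LOO = 1 - PRESS/TSS with TSS about the training mean.
    Returns a dict with q2_loo, press, rmse_cv, mae_cv, ccc_cv.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    model = fit_ols(X, y)
    tss = model.tss_tr
    if tss <= 1e-300:
        raise UndefinedStatisticError("Q2_LOO undefined: zero response variance")
    h = hat_diagonal(X)
    if np.any(h >= 1.0 - 1e-12):
        raise UndefinedStatisticError("Q2_LOO undefined: leverage of 1")
    e_del = model.residuals / (1.0 - h)
    press = float(e_del @ e_del)
    y_del = y - e_del  # deleted predictions
    n = len(y)
    return {
        "q2_loo": 1.0 - press / tss,
        "press": press,
        "rmse_cv": float(np.sqrt(press / n)),
        "mae_cv": float(np.abs(e_del).mean()),
        "ccc_cv": ccc(y, y_del),
    }


def q2_loo_brute(X, y) -> float:
    """Brute-force LOO by n refits — the independent oracle for q2_loo."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        D = _design(X[keep])
        beta, *_ = np.linalg.lstsq(D, y[keep], rcond=None)
        pred = _design(X[i : i + 1]) @ beta
        press += float((y[i] - pred[0]) ** 2)
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def q2_lmo(
    X,
    y,
    leave_fraction: float = 0.3,
    n_iter: int = 1000,
    seed: int = 0,
    exhaustive_loo: bool = False,
) -> float:
    """Leave-many-out CV: mean of 1 - PRESS_g/TSS_g over deletion groups.

    Each iteration deletes ``round(leave_fraction * n)`` rows at random
    (without replacement), refits on the rest, and scores the deleted
    rows about the retained mean.  ``exhaustive_loo=True`` instead
    deletes each single row once, reproducing Q²_LOO exactly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if exhaustive_loo:
        groups = [np.array([i]) for i in range(n)]
    else:
        n_out = max(1, int(round(leave_fraction * n)))
        if n - n_out < p + 2:
            raise UndefinedStatisticError(
                f"LMO infeasible: leaving {n_out} out of {n} rows keeps fewer "
                f"than p+2={p + 2}"
            )
        rng = np.random.default_rng(seed)
        groups = [
            np.sort(rng.choice(n, size=n_out, replace=False))
            for _ in range(n_iter)
        ]
    vals = []
    idx = np.arange(n)
    for out in groups:
        keep = ~np.isin(idx, out)
        D = _design(X[keep])
        beta, *_ = np.linalg.lstsq(D, y[keep], rcond=None)
        pred = _design(X[out]) @ beta
        press_g = float(((y[out] - pred) ** 2).sum())
        tss_g = float(((y[out] - y[keep].mean()) ** 2).sum())
        if tss_g <= 1e-300:
            continue
        vals.append(1.0 - press_g / tss_g)
    if not vals:
        raise UndefinedStatisticError("LMO produced no scorable groups")
    if exhaustive_loo:
        # aggregate as pooled PRESS/TSS to match the LOO identity
        return q2_loo(X, y)["q2_loo"]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# external validation


def _through_origin_r20(y_obs, y_pred):
    """k and r²0 for the through-origin regression of y_obs on y_pred."""
    k = float((y_obs * y_pred).sum() / (y_pred * y_pred).sum())
    ss = float(((y_obs - k * y_pred) ** 2).sum())
    tss = float(((y_obs - y_obs.mean()) ** 2).sum())
    return k, 1.0 - ss / tss


def rm2_metrics(y_obs, y_pred) -> dict:
    """Roy's r²m pair: computed in both regression directions, with the
    average and the absolute difference.  NaN when either vector is
    constant (the correlations are undefined)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.std() <= 1e-12 or y_pred.std() <= 1e-12:
        nan = float("nan")
        return {"rm2": nan, "rm2_reverse": nan, "rm2_avg": nan, "rm2_delta": nan}
    r = np.corrcoef(y_obs, y_pred)[0, 1]
    r2 = float(r * r)
    _, r20 = _through_origin_r20(y_obs, y_pred)
    _, r20_rev = _through_origin_r20(y_pred, y_obs)
    rm2 = r2 * (1.0 - np.sqrt(max(r2 - r20, 0.0)))
    rm2_rev = r2 * (1.0 - np.sqrt(max(r2 - r20_rev, 0.0)))
    return {
        "rm2": float(rm2),
        "rm2_reverse": float(rm2_rev),
        "rm2_avg": float((rm2 + rm2_rev) / 2.0),
        "rm2_delta": float(abs(rm2 - rm2_rev)),
    }


def golbraikh_tropsha(y_obs, y_pred, q2_loo_value: float) -> dict:
    """The Golbraikh-Tropsha external-predictivity checklist."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.std() <= 1e-12 or y_pred.std() <= 1e-12:
        return {
            "q2_loo_gt_0.5": bool(q2_loo_value > 0.5),
            "r2_ext_gt_0.6": False,
            "r20_gap_lt_0.1": False,
            "slope_in_0.85_1.15": False,
            "all_pass": False,
            "k": float("nan"),
            "k_reverse": float("nan"),
        }
    r = np.corrcoef(y_obs, y_pred)[0, 1]
    r2 = float(r * r)
    k, r20 = _through_origin_r20(y_obs, y_pred)
    k_rev, r20_rev = _through_origin_r20(y_pred, y_obs)
    crit = {
        "q2_loo_gt_0.5": bool(q2_loo_value > 0.5),
        "r2_ext_gt_0.6": bool(r2 > 0.6),
        "r20_gap_lt_0.1": bool((r2 - r20) / r2 < 0.1 or (r2 - r20_rev) / r2 < 0.1),
        "slope_in_0.85_1.15": bool(0.85 <= k <= 1.15 or 0.85 <= k_rev <= 1.15),
    }
    crit["all_pass"] = all(crit.values())
    crit["k"] = float(k)
    crit["k_reverse"] = float(k_rev)
    return crit


def external_validation(model: MLRModel, Xext, yext) -> dict:
    """External-set predictivity block.

    Q²_F1 scales squared prediction error by the external TSS about the
    *training* mean; Q²_F2 about the external mean; Q²_F3 compares
    per-compound mean squared error to the training-set variance.
    """
    Xext = np.asarray(Xext, dtype=float)
    yext = np.asarray(yext, dtype=float)
    if len(yext) < 3:
        raise UndefinedStatisticError("external validation needs >= 3 compounds")
    yhat = model.predict(Xext)
    press_ext = float(((yhat - yext) ** 2).sum())
    tss_tr_mean = float(((yext - model.y_train_mean) ** 2).sum())
    tss_ext = float(((yext - yext.mean()) ** 2).sum())
    if tss_ext <= 1e-300 or tss_tr_mean <= 1e-300:
        raise UndefinedStatisticError("external validation: degenerate variance")
    if yhat.std() <= 1e-12:
        r = float("nan")  # constant predictions: correlation undefined
    else:
        r = np.corrcoef(yext, yhat)[0, 1]
    out = {
        "r2_ext": float(r * r),
        "q2_f1": 1.0 - press_ext / tss_tr_mean,
        "q2_f2": 1.0 - press_ext / tss_ext,
        "q2_f3": 1.0
        - (press_ext / len(yext)) / (model.tss_tr / model.n_train),
        "ccc_ex": ccc(yext, yhat),
        "rmse_ext": float(np.sqrt(press_ext / len(yext))),
        "mae_ext": float(np.abs(yhat - yext).mean()),
    }
    out.update(rm2_metrics(yext, yhat))
    out["golbraikh_tropsha"] = golbraikh_tropsha(
        yext, yhat, q2_loo_value=np.nan
    )  # caller may re-run with the true Q2_LOO
    return out


# ---------------------------------------------------------------------------
# chance correlation


def y_randomization(
    X, y, n_iter: int = 2000, seed: int = 0, permutations=None
) -> dict:
    """Refit after shuffling the response; collect scrambled R² and Q²_LOO.

    A sound model's scrambled R² distribution sits far below the real
    fit.  ``permutations`` overrides the random draws (used to force,
    e.g., the identity permutation in tests).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if permutations is None:
        if n_iter == 0:
            return {
                "r2": np.array([]),
                "q2": np.array([]),
                "no_op": True,
                "n_iter": 0,
            }
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(len(y)) for _ in range(n_iter)]
    r2s, q2s = [], []
    for perm in permutations:
        yp = y[np.asarray(perm)]
        m = fit_ols(X, yp)
        r2s.append(m.r2)
        q2s.append(q2_loo(X, yp)["q2_loo"])
    r2s = np.array(r2s)
    q2s = np.array(q2s)
    return {
        "r2": r2s,
        "q2": q2s,
        "r2_mean": float(r2s.mean()),
        "r2_max": float(r2s.max()),
        "q2_mean": float(q2s.mean()),
        "q2_max": float(q2s.max()),
        "no_op": False,
        "n_iter": len(r2s),
    }


# ---------------------------------------------------------------------------
# QUIK rule


def k_index(M: np.ndarray) -> float:
    """Todeschini's multivariate K correlation index of a column block.

    K = Σ_j |λ_j/Σλ − 1/m| / (2(m−1)/m) over the eigenvalues of the
    column correlation matrix; 0 for mutually orthogonal columns, 1 for
    perfectly collinear ones.
    """
    M = np.asarray(M, dtype=float)
    m = M.shape[1]
    if m < 2:
        raise UndefinedStatisticError("K index needs >= 2 columns")
    sd = M.std(axis=0)
    if np.any(sd <= 1e-300):
        raise UndefinedStatisticError("K index undefined for constant columns")
    C = np.corrcoef(M, rowvar=False)
    lam = np.linalg.eigvalsh(C)
    lam = np.clip(lam, 0.0, None)
    frac = lam / lam.sum()
    return float(np.abs(frac - 1.0 / m).sum() / (2.0 * (m - 1) / m))


def quik_check(Xtr, ytr, delta: float = 0.05) -> dict:
    """QUIK rule: pass iff K_xxy − K_xx ≥ delta.

    K_xx is the K index of the descriptor block, K_xxy of the block
    augmented with the response; a model whose response adds too little
    multivariate correlation is rejected as redundancy-driven.
    """
    Xtr = np.asarray(Xtr, dtype=float)
    ytr = np.asarray(ytr, dtype=float)
    kxx = k_index(Xtr)
    kxxy = k_index(np.column_stack([Xtr, ytr]))
    return {
        "k_xx": kxx,
        "k_xxy": kxxy,
        "delta": delta,
        "pass": bool(kxxy - kxx >= delta),
    }


# ---------------------------------------------------------------------------
# applicability domain


def applicability_domain(
    model: MLRModel,
    Xtr,
    ytr,
    Xq=None,
    yq=None,
    resid_cutoff: float = 3.0,
) -> pd.DataFrame:
    """Williams-plot data and outlier labels.

    Leverage h_i = x_i (XᵀX)⁻¹ x_iᵀ with the intercept column; the
    warning leverage is h* = 3(p+1)/n_train.  Training residuals are
    internally studentized; query residuals (when yq is given) are
    scaled by the training s.  Labels:

    * ``X_outlier`` — h > h* (structurally outside the domain);
    * ``Y_outlier`` — |standardized residual| > cutoff;
    * ``model_outlier`` — inside both margins yet with a deletion
      residual > cutoff × RMSE_cv (visible only once the model exists);
    * ``inside`` otherwise.

    X and Y flags may co-occur; the combined case is labelled
    ``XY_outlier``.
    """
    Xtr = np.asarray(Xtr, dtype=float)
    if Xtr.ndim == 1:
        Xtr = Xtr[:, None]
    ytr = np.asarray(ytr, dtype=float)
    n, p = Xtr.shape
    h_star = 3.0 * (p + 1) / n

    D = _design(Xtr)
    XtX_inv = np.linalg.inv(D.T @ D)
    h_tr = np.einsum("ij,jk,ik->i", D, XtX_inv, D)
    resid = ytr - model.predict(Xtr)
    std_resid = resid / (model.s * np.sqrt(np.clip(1.0 - h_tr, 1e-12, None)))
    e_del = resid / np.clip(1.0 - h_tr, 1e-12, None)
    loo = q2_loo(Xtr, ytr)
    rmse_cv = loo["rmse_cv"]

    rows = []
    for i in range(n):
        rows.append(
            _ad_row(
                f"train_{i}",
                "train",
                h_tr[i],
                std_resid[i],
                h_star,
                resid_cutoff,
                deletion_resid=e_del[i],
                rmse_cv=rmse_cv,
            )
        )
    if Xq is not None:
        Xq = np.asarray(Xq, dtype=float)
        if Xq.ndim == 1:
            Xq = Xq[:, None]
        Dq = _design(Xq)
        h_q = np.einsum("ij,jk,ik->i", Dq, XtX_inv, Dq)
        if yq is not None:
            rq = np.asarray(yq, dtype=float) - model.predict(Xq)
            sr_q = rq / model.s
        else:
            sr_q = np.full(len(Xq), np.nan)
        for i in range(len(Xq)):
            rows.append(
                _ad_row(
                    f"query_{i}", "query", h_q[i], sr_q[i], h_star, resid_cutoff
                )
            )
    df = pd.DataFrame(rows)
    df.attrs["h_star"] = h_star
    df.attrs["resid_cutoff"] = resid_cutoff
    return df


def _ad_row(
    cid,
    role,
    h,
    std_resid,
    h_star,
    cutoff,
    deletion_resid=np.nan,
    rmse_cv=np.nan,
):
    x_out = bool(h > h_star)
    y_out = bool(np.isfinite(std_resid) and abs(std_resid) > cutoff)
    if x_out and y_out:
        label = "XY_outlier"
    elif x_out:
        label = "X_outlier"
    elif y_out:
        label = "Y_outlier"
    elif (
        np.isfinite(deletion_resid)
        and np.isfinite(rmse_cv)
        and abs(deletion_resid) > cutoff * rmse_cv
    ):
        label = "model_outlier"
    else:
        label = "inside"
    return {
        "compound": cid,
        "role": role,
        "leverage": float(h),
        "std_residual": float(std_resid) if np.isfinite(std_resid) else np.nan,
        "label": label,
    }


# ---------------------------------------------------------------------------
# the full battery


def validate_model(
    subset_X_tr,
    y_tr,
    subset_X_ext=None,
    y_ext=None,
    descriptor_names=None,
    lmo_fraction: float = 0.3,
    lmo_iters: int = 1000,
    yrand_iters: int = 2000,
    quik_delta: float = 0.05,
    resid_cutoff: float = 3.0,
    seed: int = 0,
) -> dict:
    """Run the complete validation battery for one descriptor subset.

    Returns a nested dict: ``model`` (the fitted MLRModel), ``internal``,
    ``external`` (when an external set is given), ``randomization``,
    ``quik`` and ``domain`` (a Williams-plot DataFrame).
    """
    model = fit_ols(subset_X_tr, y_tr, descriptor_names=descriptor_names)
    internal = q2_loo(subset_X_tr, y_tr)
    internal["q2_lmo"] = q2_lmo(
        subset_X_tr,
        y_tr,
        leave_fraction=lmo_fraction,
        n_iter=lmo_iters,
        seed=seed,
    )
    report = {
        "model": model,
        "internal": internal,
        "randomization": y_randomization(
            subset_X_tr, y_tr, n_iter=yrand_iters, seed=seed
        ),
        "quik": quik_check(subset_X_tr, y_tr, delta=quik_delta)
        if np.asarray(subset_X_tr).ndim == 2
        and np.asarray(subset_X_tr).shape[1] >= 2
        else None,
    }
    if subset_X_ext is not None and y_ext is not None:
        ext = external_validation(model, subset_X_ext, y_ext)
        ext["golbraikh_tropsha"] = golbraikh_tropsha(
            np.asarray(y_ext, dtype=float),
            model.predict(np.asarray(subset_X_ext, dtype=float)),
            q2_loo_value=internal["q2_loo"],
        )
        report["external"] = ext
        report["domain"] = applicability_domain(
            model, subset_X_tr, y_tr, subset_X_ext, y_ext,
            resid_cutoff=resid_cutoff,
        )
    else:
        report["domain"] = applicability_domain(
            model, subset_X_tr, y_tr, resid_cutoff=resid_cutoff
        )
    return report
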