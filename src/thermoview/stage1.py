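"""Stage-1 variance decomposition of multi-view canopy-temperature records.

Each per-image per-plot measurement is decomposed additively into

    value = mu + genotype + treatment + (genotype x treatment)
            + replicate [+ treatment x replicate] + plot
            + spatial(row, col) + f_spl(trigger) + residual

with the temporal trend modelled as a penalized cubic spline per flight over
the ordered trigger events (thermal drift of the uncooled sensor), and the
spatial trend as a separable AR(1)xAR(1) Gaussian field over the plot grid,
BLUP-estimated with variance parameters from marginal maximum likelihood.

Estimation is by backfitting (cyclic partial-residual updates): design-factor
means (genotype and plot shrunken as random effects, treatment and replicate
unshrunken), then the P-spline with a GCV-chosen penalty, then the spatial
field, iterated to a fixed point.  Identifiability: every effect family is
centred and the grand mean carries the level.  Absolute temperatures are
never interpreted downstream — only relative differences.

The fitted model yields the plot-wise prediction chain used throughout:

* ``mean``   — raw per-plot mean over all images (no model),
* ``t_c``    — temporally corrected (spline omitted),
* ``ts_c``   — temporally and spatially corrected (spatial also omitted),
* ``t_defl`` — ``ts_c`` with the plot's treatment effect removed, leaving
  genotype, genotype-by-treatment interaction, plot and replicate signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "Stage1Config",
    "CanopyTemperatureModel",
    "Stage1Results",
    "fit_stage1",
    "predict",
    "spatial_trend",
    "variance_table",
    "repeatability",
    "PREDICTION_LEVELS",
]

PREDICTION_LEVELS = ("mean", "t_c", "ts_c", "t_defl")


@dataclass
class Stage1Config:
    """Tunable knobs of the stage-1 fit.

    ``spline_knot_spacing`` is in trigger events (a knot every ~10 images);
    the penalty weight is chosen by generalized cross-validation from
    ``spline_lambdas``.  ``tol`` (K) bounds the largest absolute change of
    any effect between backfitting sweeps.
    """

    include_interaction: bool = True
    include_treatment_by_replicate: bool = False
    spline_knot_spacing: int = 10
    spline_lambdas: tuple = tuple(float(x) for x in np.logspace(-4, 5, 13))
    rho_init: float = 0.5
    max_iter: int = 200
    tol: float = 1e-6
    shrink_genotype: bool = True


# ---------------------------------------------------------------------------
# penalized spline
# ---------------------------------------------------------------------------

def _spline_design(T: int, knot_spacing: int):
    """Cubic B-spline basis at integer points 0..T-1 plus D2 penalty matrix.

    One knot segment per ``knot_spacing`` triggers; the basis degrades
    gracefully for very short flights (linear below 5 triggers, a plain
    intercept for a single trigger).
    """
    if T == 1:
        return np.ones((1, 1)), np.zeros((1, 1))
    n_seg = max(1, int(round((T - 1) / knot_spacing)))
    n_seg = min(n_seg, max(1, T - 3))  # keep basis under the data size
    degree = 3 if T > 4 else 1
    inner = np.linspace(0.0, T - 1.0, n_seg + 1)
    knots = np.concatenate(
        [np.full(degree, inner[0]), inner, np.full(degree, inner[-1])]
    )
    x = np.arange(T, dtype=float)
    B = BSpline.design_matrix(x, knots, degree).toarray()
    k = B.shape[1]
    if k >= 3:
        D = np.diff(np.eye(k), n=2, axis=0)
    else:
        D = np.zeros((1, k))
    return B, D.T @ D


def _block_diag_dense(mats):
    sizes = [m.shape[0] for m in mats]
    out = np.zeros((sum(sizes), sum(sizes)))
    pos = 0
    for m in mats:
        out[pos:pos + m.shape[0], pos:pos + m.shape[0]] = m
        pos += m.shape[0]
    return out


def _pspline(t_idx, y, w, knot_spacing, lambdas):
    """Weighted P-spline fit over integer trigger index.

    Cubic B-spline basis with evenly spaced knots (one segment per
    ``knot_spacing`` triggers), second-difference coefficient penalty,
    penalty weight by GCV over ``lambdas``.  Returns (fitted values,
    chosen lambda).
    """
    T = len(y)
    if T == 1:
        return np.array([y[0]]), lambdas[0]
    B_full, P = _spline_design(T, knot_spacing)
    idx = np.asarray(t_idx, dtype=int)
    B = B_full[idx]
    W = np.asarray(w, dtype=float)
    BtW = B.T * W
    BtWB = BtW @ B
    BtWy = BtW @ np.asarray(y, dtype=float)
    n_eff = W.sum()

    best = None
    for lam in lambdas:
        A = BtWB + lam * P
        try:
            coef = np.linalg.solve(A, BtWy)
            H_tr = float(np.trace(np.linalg.solve(A, BtWB)))
        except np.linalg.LinAlgError:
            continue
        fit = B @ coef
        rss = float(W @ (y - fit) ** 2)
        denom = max(n_eff - H_tr, 1e-8)
        gcv = n_eff * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, fit, lam)
    if best is None:  # fully singular: fall back to the weighted mean
        fit = np.full(T, float(np.average(y, weights=W)))
        return fit, lambdas[0]
    return best[1], best[2]


# ---------------------------------------------------------------------------
# spatial AR(1) x AR(1) field
# ---------------------------------------------------------------------------

def _spatial_corr(rows, cols, rho_r, rho_c):
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    return (rho_r**dr) * (rho_c**dc)


def _fit_spatial_variances(u, m, rows, cols, sigma_e2, rho_init):
    """Marginal-ML variance parameters for u = spatial + plot + mean-noise.

    Parametrization: log sigma_s^2, atanh rho_row, atanh rho_col,
    log sigma_phi^2.  Returns (sigma_s2, rho_r, rho_c, sigma_phi2).
    """
    n = len(u)
    u = np.asarray(u, dtype=float)
    noise_diag = sigma_e2 / np.maximum(m, 1)
    var_u = max(float(np.var(u)), 1e-12)

    def nll(theta):
        s2 = math_exp(theta[0])
        phi2 = math_exp(theta[3])
        rr = float(np.clip(np.tanh(theta[1]), -0.985, 0.985))
        rc = float(np.clip(np.tanh(theta[2]), -0.985, 0.985))
        V = s2 * _spatial_corr(rows, cols, rr, rc)
        V[np.diag_indices(n)] += phi2 + noise_diag
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        alpha = np.linalg.solve(L, u)
        return float(np.log(np.diag(L)).sum() + 0.5 * alpha @ alpha)

    x0 = np.array(
        [np.log(var_u / 2 + 1e-10), np.arctanh(rho_init), np.arctanh(rho_init),
         np.log(var_u / 4 + 1e-10)]
    )
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-7})
    s2 = math_exp(res.x[0])
    phi2 = math_exp(res.x[3])
    rr = float(np.clip(np.tanh(res.x[1]), -0.985, 0.985))
    rc = float(np.clip(np.tanh(res.x[2]), -0.985, 0.985))
    return s2, rr, rc, phi2


def math_exp(x):
    return float(np.exp(np.clip(x, -40, 40)))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CanopyTemperatureModel:
    """Additive decomposition model for multi-view CT measurements.

    Parameters
    ----------
    measurements : DataFrame
        Long-format (plot x trigger) records; needs columns plot_id,
        trigger_id, time_s, value_K and optionally flight_id (single flight
        assumed when absent).  Multiple flights of a campaign are pooled with
        one spline per flight and shared design/spatial structure.
    layout : FieldLayout
        Plot grid with genotype/treatment/replicate assignment.
    config : Stage1Config, optional
    """

    def __init__(self, measurements: pd.DataFrame, layout, config: Stage1Config | None = None):
        self.config = config or Stage1Config()
        self.layout = layout
        df = measurements.copy()
        if "flight_id" not in df.columns:
            df["flight_id"] = "F1"
        meta = layout.plots.set_index("plot_id")
        missing = set(df["plot_id"]) - set(meta.index)
        if missing:
            raise ValueError(f"measurements reference unknown plots: {sorted(missing)[:5]}")
        counts = df.groupby("plot_id").size()
        frac_ok = (counts >= 2).mean()
        if frac_ok < 0.8 and counts.max() > 1:
            logger.warning(
                "only %.0f%% of measured plots have >= 2 records", 100 * frac_ok
            )
        singletons = (
            meta.loc[~meta["is_border"]].groupby("genotype").size() == 1
        )
        for g in singletons[singletons].index:
            logger.warning(
                "genotype %s appears in a single plot; its effect is confounded "
                "with the plot term", g,
            )
        self.data = df

    def fit(self) -> "Stage1Results":
        cfg = self.config
        df = self.data
        meta = self.layout.plots.set_index("plot_id")
        y = df["value_K"].to_numpy(dtype=float)
        n = y.size

        plot_ids, plot_code = np.unique(df["plot_id"].to_numpy(), return_inverse=True)
        pmeta = meta.loc[plot_ids]
        geno_of_plot = pmeta["genotype"].to_numpy()
        treat_of_plot = pmeta["treatment"].to_numpy()
        rep_of_plot = pmeta["replicate"].to_numpy().astype(object)
        border_plot = pmeta["is_border"].to_numpy()
        rows = pmeta["row"].to_numpy(dtype=float)
        cols = pmeta["col"].to_numpy(dtype=float)

        geno_levels, geno_of_plot_code = np.unique(geno_of_plot, return_inverse=True)
        treat_levels, treat_of_plot_code = np.unique(treat_of_plot, return_inverse=True)
        rep_levels, rep_of_plot_code = np.unique(rep_of_plot, return_inverse=True)

        g_rec = geno_of_plot_code[plot_code]
        k_rec = treat_of_plot_code[plot_code]
        r_rec = rep_of_plot_code[plot_code]

        # interaction levels only for experiment plots
        inter_key = np.where(
            border_plot, "__none__",
            pd.Series(geno_of_plot).astype(str) + ":" + pd.Series(treat_of_plot).astype(str),
        )
        inter_levels, inter_of_plot_code = np.unique(inter_key, return_inverse=True)
        i_rec = inter_of_plot_code[plot_code]
        inter_is_none = inter_levels == "__none__"

        taurep_key = (
            pd.Series(treat_of_plot).astype(str) + "|" + pd.Series(rep_of_plot).astype(str)
        ).to_numpy()
        taurep_key = np.where(border_plot, "__none__", taurep_key)
        taurep_levels, taurep_of_plot_code = np.unique(taurep_key, return_inverse=True)
        tr_rec = taurep_of_plot_code[plot_code]

        # per-flight trigger indexing, ordered by time
        flights, flight_code = np.unique(df["flight_id"].to_numpy(), return_inverse=True)
        trig_key = list(zip(df["flight_id"].to_numpy(), df["trigger_id"].to_numpy()))
        trig_frame = (
            df[["flight_id", "trigger_id", "time_s"]]
            .drop_duplicates(["flight_id", "trigger_id"])
            .sort_values(["flight_id", "time_s"], kind="mergesort")
            .reset_index(drop=True)
        )
        trig_frame["t_idx"] = trig_frame.groupby("flight_id").cumcount()
        trig_lookup = {
            (f, t): j for j, (f, t) in enumerate(
                zip(trig_frame["flight_id"], trig_frame["trigger_id"])
            )
        }
        j_rec = np.fromiter((trig_lookup[k] for k in trig_key), dtype=int, count=n)
        n_trig = len(trig_frame)
        trig_flight = trig_frame["flight_id"].to_numpy()
        trig_tidx = trig_frame["t_idx"].to_numpy()

        m_plot = np.bincount(plot_code, minlength=len(plot_ids)).astype(float)

        # ---------------- state ----------------
        mu = float(y.mean())
        geno = np.zeros(len(geno_levels))
        treat = np.zeros(len(treat_levels))
        inter = np.zeros(len(inter_levels))
        rep = np.zeros(len(rep_levels))
        taurep = np.zeros(len(taurep_levels))
        phi = np.zeros(len(plot_ids))
        spatial = np.zeros(len(plot_ids))
        spline = np.zeros(n_trig)
        flight_off = np.zeros(len(flights))

        sigma_e2 = max(float(np.var(y)), 1e-12)
        spat_params = None
        exp_geno_mask = geno_levels != "border"

        def design_rec():
            out = mu + geno[g_rec] + treat[k_rec] + rep[r_rec]
            if cfg.include_interaction:
                out = out + inter[i_rec]
            if cfg.include_treatment_by_replicate:
                out = out + taurep[tr_rec]
            return out

        def snapshot():
            return np.concatenate(
                [[mu], geno, treat, inter, rep, taurep, phi, spatial, spline, flight_off]
            )

        part_sizes = [1, len(geno_levels), len(treat_levels), len(inter_levels),
                      len(rep_levels), len(taurep_levels), len(plot_ids),
                      len(plot_ids), n_trig, len(flights)]
        bounds = np.cumsum(part_sizes)

        def unpack(v):
            parts = np.split(v, bounds[:-1])
            return (float(parts[0][0]),) + tuple(parts[1:])

        # Backfitting sweeps serve as a warm-up that estimates the adaptive
        # hyperparameters (shrinkage ratios, GCV spline penalty, variance
        # components); the final estimates then come from an exact joint
        # penalized GLS solve, which is immune to the slow Gauss-Seidel
        # convergence caused by temporal/spatial confounding of a
        # serpentine flight path.
        warmup = 2
        lam_g = 0.0
        lam_i = 0.0
        spline_lam = {}

        last_delta = np.inf
        converged = False
        for it in range(warmup + 1):
            prev = snapshot()

            # ---- design effects (cyclic shrunken/plain means) ----
            # Updates run on plot-level means so every plot carries equal
            # weight: the plot is the experimental unit, and record counts
            # per plot vary with the flight pattern.
            base_rec = y - spline[j_rec] - flight_off[flight_code]
            u_base = (
                np.bincount(plot_code, base_rec, minlength=len(plot_ids))
                / np.maximum(m_plot, 1.0)
                - spatial - phi
            )
            gp = geno_of_plot_code
            kp = treat_of_plot_code
            rp = rep_of_plot_code
            ip = inter_of_plot_code
            trp = taurep_of_plot_code

            _, _, _, phi2_cur = spat_params or (0.0, 0.0, 0.0, 0.0)
            s2_lvl = phi2_cur + sigma_e2 / max(float(m_plot.mean()), 1.0)
            if cfg.shrink_genotype and 0 < it <= warmup:
                var_g = max(float(np.var(geno[exp_geno_mask])), 1e-12)
                lam_g = min(s2_lvl / var_g, 1e8)

            def others(skip):
                out = np.full(len(plot_ids), mu)
                if skip != "geno":
                    out = out + geno[gp]
                if skip != "treat":
                    out = out + treat[kp]
                if skip != "rep":
                    out = out + rep[rp]
                if cfg.include_interaction and skip != "inter":
                    out = out + inter[ip]
                if cfg.include_treatment_by_replicate and skip != "taurep":
                    out = out + taurep[trp]
                return out

            part = u_base - others("geno")
            sums = np.bincount(gp, part, minlength=len(geno_levels))
            cnts = np.bincount(gp, minlength=len(geno_levels)).astype(float)
            geno = sums / np.maximum(cnts + lam_g, 1.0)
            off = geno[exp_geno_mask].mean() if exp_geno_mask.any() else geno.mean()
            geno -= off
            mu += off

            part = u_base - others("treat")
            sums = np.bincount(kp, part, minlength=len(treat_levels))
            cnts = np.bincount(kp, minlength=len(treat_levels)).astype(float)
            treat = sums / np.maximum(cnts, 1.0)
            exp_treat_mask = treat_levels != "border"
            off = treat[exp_treat_mask].mean() if exp_treat_mask.any() else treat.mean()
            treat -= off
            mu += off

            if cfg.include_interaction:
                part = u_base - others("inter")
                sums = np.bincount(ip, part, minlength=len(inter_levels))
                cnts = np.bincount(ip, minlength=len(inter_levels)).astype(float)
                # interaction shrunken like a random effect so that a near-zero
                # interaction variance forces the cells to zero instead of
                # letting them absorb genotype main effects
                if 0 < it <= warmup:
                    var_i = max(float(np.var(inter[~inter_is_none])), 1e-12)
                    lam_i = min(s2_lvl / var_i, 1e8)
                inter = sums / np.maximum(cnts + lam_i, 1.0)
                inter[inter_is_none] = 0.0
                mask = ~inter_is_none
                if mask.any():
                    off = inter[mask].mean()
                    inter[mask] -= off
                    mu += off

            part = u_base - others("rep")
            sums = np.bincount(rp, part, minlength=len(rep_levels))
            cnts = np.bincount(rp, minlength=len(rep_levels)).astype(float)
            rep = sums / np.maximum(cnts, 1.0)
            off = rep.mean()
            rep -= off
            mu += off

            if cfg.include_treatment_by_replicate:
                part = u_base - others("taurep")
                sums = np.bincount(trp, part, minlength=len(taurep_levels))
                cnts = np.bincount(trp, minlength=len(taurep_levels)).astype(float)
                taurep = sums / np.maximum(cnts, 1.0)
                taurep[taurep_levels == "__none__"] = 0.0
                mask = taurep_levels != "__none__"
                if mask.any():
                    off = taurep[mask].mean()
                    taurep[mask] -= off
                    mu += off

            # ---- temporal spline (per flight) ----
            part = y - design_rec() - spatial[plot_code] - phi[plot_code]
            t_sum = np.bincount(j_rec, part, minlength=n_trig)
            t_cnt = np.bincount(j_rec, minlength=n_trig).astype(float)
            t_mean = t_sum / np.maximum(t_cnt, 1.0)
            for fi, f in enumerate(flights):
                sel = trig_flight == f
                w = t_cnt[sel]
                grid = (
                    cfg.spline_lambdas
                    if it <= warmup or f not in spline_lam
                    else (spline_lam[f],)
                )
                fitted, lam_used = _pspline(
                    trig_tidx[sel], t_mean[sel], np.maximum(w, 1e-9),
                    cfg.spline_knot_spacing, grid,
                )
                spline_lam[f] = lam_used
                offset = float(fitted.mean())
                spline[sel] = fitted - offset
                flight_off[fi] = offset
            off = float(np.average(flight_off, weights=np.bincount(flight_code).astype(float)))
            flight_off -= off
            mu += off

            # ---- spatial field + plot effects ----
            part = y - design_rec() - spline[j_rec] - flight_off[flight_code]
            u_sum = np.bincount(plot_code, part, minlength=len(plot_ids))
            u = u_sum / np.maximum(m_plot, 1.0)
            if it <= warmup:
                within = part - u[plot_code]
                dof = max(n - len(plot_ids), 1)
                sigma_e2 = max(
                    float(within @ within) / dof, 1e-8 * float(np.var(y)), 1e-12
                )  # relative floor keeps penalty ratios numerically meaningful

            if it <= warmup or spat_params is None:
                spat_params = _fit_spatial_variances(
                    u, m_plot, rows, cols, sigma_e2, cfg.rho_init
                )
            s2, rho_r, rho_c, phi2 = spat_params
            if s2 + phi2 > 1e-10:
                K = _spatial_corr(rows, cols, rho_r, rho_c)
                V = s2 * K
                V[np.diag_indices(len(u))] += phi2 + sigma_e2 / np.maximum(m_plot, 1.0)
                alpha = np.linalg.solve(V, u)
                spatial = s2 * (K @ alpha)
                phi = phi2 * alpha
            else:
                spatial = np.zeros(len(plot_ids))
                phi = np.zeros(len(plot_ids))

            last_delta = float(np.max(np.abs(snapshot() - prev)))

        # ---- exact joint solve -------------------------------------------
        # Unknowns: intercept, design-effect levels (with ridge shrinkage on
        # the random families), per-flight spline coefficients (with the
        # GCV-chosen second-difference penalty) and the combined plot-level
        # random effect v = spatial + plot (with prior sigma_s^2 K + phi^2 I).
        from scipy import sparse

        logger.debug(
            "warm-up done: lam_g=%.3e lam_i=%.3e sigma_e2=%.3e spat=%s",
            lam_g, lam_i, sigma_e2, spat_params,
        )
        eps = 1e-10 * max(n, 100)

        def indicator(codes, n_levels):
            return sparse.csr_matrix(
                (np.ones(len(codes)), (np.arange(len(codes)), codes)),
                shape=(len(codes), n_levels),
            )

        X_int = sparse.csr_matrix(np.ones((n, 1)))
        X_g = indicator(g_rec, len(geno_levels))
        X_k = indicator(k_rec, len(treat_levels))
        X_r = indicator(r_rec, len(rep_levels))
        inter_keep = np.nonzero(~inter_is_none)[0]
        X_i = indicator(i_rec, len(inter_levels))[:, inter_keep]
        taurep_keep = np.nonzero(taurep_levels != "__none__")[0]
        X_tr = indicator(tr_rec, len(taurep_levels))[:, taurep_keep]

        spline_bases = {}
        sp_blocks, sp_pens = [], []
        for f in flights:
            sel = trig_flight == f
            Tf = int(sel.sum())
            Bf, Pf = _spline_design(Tf, cfg.spline_knot_spacing)
            spline_bases[f] = (sel, Bf)
            sp_blocks.append(sparse.csr_matrix(Bf))
            lam_f = spline_lam.get(f, cfg.spline_lambdas[len(cfg.spline_lambdas) // 2])
            sp_pens.append(lam_f * Pf + eps * np.eye(Pf.shape[0]))
        B_all = sparse.block_diag(sp_blocks, format="csr")
        X_spl = indicator(j_rec, n_trig) @ B_all
        X_v = indicator(plot_code, len(plot_ids))

        # record-level mixed-model ridges: sigma_e^2 / sigma_family^2
        if cfg.shrink_genotype:
            var_g = max(float(np.var(geno[exp_geno_mask])), 1e-12)
            lam_g_rec = min(sigma_e2 / var_g, 1e8)
        else:
            lam_g_rec = 0.0
        var_i = max(float(np.var(inter[~inter_is_none])), 1e-12) if len(inter_keep) else 1.0
        lam_i_rec = min(sigma_e2 / var_i, 1e8)

        blocks = [X_int, X_g, X_k, X_r]
        pens = [
            np.array([[eps]]),
            (lam_g_rec + eps) * np.eye(len(geno_levels)),
            eps * np.eye(len(treat_levels)),
            eps * np.eye(len(rep_levels)),
        ]
        if cfg.include_interaction and len(inter_keep):
            blocks.append(X_i)
            pens.append((lam_i_rec + eps) * np.eye(len(inter_keep)))
        if cfg.include_treatment_by_replicate and len(taurep_keep):
            blocks.append(X_tr)
            pens.append(eps * np.eye(len(taurep_keep)))
        blocks.append(X_spl)
        pens.append(_block_diag_dense(sp_pens))
        blocks.append(X_v)

        sizes = [b.shape[1] for b in blocks]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        M = sparse.hstack(blocks, format="csr")
        MtM = (M.T @ M).toarray()
        Mty = M.T @ y

        for jt in range(max(3, min(cfg.max_iter, 10))):
            prev = snapshot()
            s2, rho_r, rho_c, phi2 = spat_params
            Sigma_v = s2 * _spatial_corr(rows, cols, rho_r, rho_c)
            Sigma_v[np.diag_indices(len(plot_ids))] += phi2
            # guard against a degenerate (near-zero) prior
            Sigma_v[np.diag_indices(len(plot_ids))] += 1e-12
            v_pen = sigma_e2 * np.linalg.inv(Sigma_v) + eps * np.eye(len(plot_ids))

            A = MtM.copy()
            for bi, pen in enumerate(pens):
                sl = slice(offsets[bi], offsets[bi] + sizes[bi])
                A[sl, sl] += pen
            A[offsets[-2]:offsets[-1], offsets[-2]:offsets[-1]] += v_pen
            theta = np.linalg.solve(A, Mty)

            # ---- unpack & recentre ----
            pos = 0
            mu = float(theta[0]); pos = 1
            geno = theta[pos:pos + len(geno_levels)].copy(); pos += len(geno_levels)
            treat = theta[pos:pos + len(treat_levels)].copy(); pos += len(treat_levels)
            rep = theta[pos:pos + len(rep_levels)].copy(); pos += len(rep_levels)
            inter = np.zeros(len(inter_levels))
            if cfg.include_interaction and len(inter_keep):
                inter[inter_keep] = theta[pos:pos + len(inter_keep)]
                pos += len(inter_keep)
            taurep = np.zeros(len(taurep_levels))
            if cfg.include_treatment_by_replicate and len(taurep_keep):
                taurep[taurep_keep] = theta[pos:pos + len(taurep_keep)]
                pos += len(taurep_keep)
            n_spl = B_all.shape[1]
            spl_coef = theta[pos:pos + n_spl]; pos += n_spl
            v = theta[pos:pos + len(plot_ids)]

            cpos = 0
            for f, blk in zip(flights, sp_blocks):
                sel, Bf = spline_bases[f]
                kf = Bf.shape[1]
                spline[sel] = Bf @ spl_coef[cpos:cpos + kf]
                cpos += kf
            # recentre: families sum to zero, spline mean-zero per flight
            for fi, f in enumerate(flights):
                sel = spline_bases[f][0]
                flight_off[fi] = float(spline[sel].mean())
                spline[sel] -= flight_off[fi]
            off = float(np.average(flight_off, weights=np.bincount(flight_code).astype(float)))
            flight_off -= off
            mu += off
            off = geno[exp_geno_mask].mean() if exp_geno_mask.any() else geno.mean()
            geno -= off; mu += off
            exp_treat_mask = treat_levels != "border"
            off = treat[exp_treat_mask].mean() if exp_treat_mask.any() else treat.mean()
            treat -= off; mu += off
            off = rep.mean(); rep -= off; mu += off
            if cfg.include_interaction and len(inter_keep):
                off = inter[inter_keep].mean(); inter[inter_keep] -= off; mu += off
            if cfg.include_treatment_by_replicate and len(taurep_keep):
                off = taurep[taurep_keep].mean(); taurep[taurep_keep] -= off; mu += off
            off = float(v.mean()); mu += off
            v = v - off
            # split v into the smooth field and the white plot effect
            if s2 + phi2 > 1e-10:
                spatial = s2 * (
                    _spatial_corr(rows, cols, rho_r, rho_c) @ np.linalg.solve(Sigma_v, v)
                )
                phi = v - spatial
            else:
                spatial = np.zeros(len(plot_ids))
                phi = v.copy()

            # ---- refresh variance parameters once, then freeze ----
            if jt == 0:
                part = y - design_rec() - spline[j_rec] - flight_off[flight_code]
                u = np.bincount(plot_code, part, minlength=len(plot_ids)) / np.maximum(m_plot, 1.0)
                within = part - u[plot_code]
                dof = max(n - len(plot_ids), 1)
                sigma_e2 = max(
                    float(within @ within) / dof, 1e-8 * float(np.var(y)), 1e-12
                )  # relative floor keeps penalty ratios numerically meaningful
                spat_params = _fit_spatial_variances(
                    u, m_plot, rows, cols, sigma_e2, cfg.rho_init
                )
            it += 1
            last_delta = float(np.max(np.abs(snapshot() - prev)))
            if last_delta < cfg.tol:
                converged = True
                break

        if not converged:
            raise RuntimeError(
                f"stage-1 estimation did not converge (last max effect change "
                f"{last_delta:.3e} K)"
            )

        fitted = design_rec() + spline[j_rec] + flight_off[flight_code] \
            + spatial[plot_code] + phi[plot_code]
        residuals = y - fitted

        raw_means = pd.Series(
            np.bincount(plot_code, y) / np.maximum(m_plot, 1.0), index=plot_ids
        )

        s2, rho_r, rho_c, phi2 = spat_params
        variance_components = {
            "genotype": float(np.var(geno[exp_geno_mask])) if exp_geno_mask.any() else 0.0,
            "treatment": float(np.var(treat[treat_levels != "border"])),
            "replicate": float(np.var(rep)),
            "plot": phi2,
            "spatial": s2,
            "residual": sigma_e2,
        }

        spline_series = pd.Series(
            spline,
            index=pd.MultiIndex.from_arrays(
                [trig_frame["flight_id"], trig_frame["trigger_id"]],
                names=["flight_id", "trigger_id"],
            ),
            name="f_spl",
        )

        effects = {
            "genotype": pd.Series(geno, index=geno_levels),
            "treatment": pd.Series(treat, index=treat_levels),
            "interaction": pd.Series(inter, index=inter_levels),
            "replicate": pd.Series(rep, index=rep_levels),
            "treatment_by_replicate": pd.Series(taurep, index=taurep_levels),
            "plot": pd.Series(phi, index=plot_ids),
            "spatial": pd.Series(spatial, index=plot_ids),
        }

        return Stage1Results(
            model=self,
            grand_mean=mu,
            effects=effects,
            spline=spline_series,
            flight_offsets=pd.Series(flight_off, index=flights),
            residuals=pd.Series(residuals, index=df.index),
            fitted=pd.Series(fitted, index=df.index),
            raw_plot_means=raw_means,
            variance_components=variance_components,
            spatial_rho=(rho_r, rho_c),
            n_iter=it + 1,
            last_delta=last_delta,
            converged=converged,
        )


@dataclass
class Stage1Results:
    """Fitted stage-1 decomposition: effects, spline, spatial field, residuals."""

    model: CanopyTemperatureModel
    grand_mean: float
    effects: dict
    spline: pd.Series
    flight_offsets: pd.Series
    residuals: pd.Series
    fitted: pd.Series
    raw_plot_means: pd.Series
    variance_components: dict
    spatial_rho: tuple
    n_iter: int
    last_delta: float
    converged: bool

    # -- prediction chain ---------------------------------------------------
    def predict(self, level: str) -> pd.DataFrame:
        """Plot-wise CT estimates at one correction level (border excluded)."""
        if level not in PREDICTION_LEVELS:
            raise ValueError(f"unknown level {level!r}; expected one of {PREDICTION_LEVELS}")
        layout = self.model.layout
        meta = layout.plots.set_index("plot_id")
        plot_ids = self.effects["plot"].index
        meta = meta.loc[meta.index.intersection(plot_ids)]
        exp = meta[~meta["is_border"]]

        if level == "mean":
            est = self.raw_plot_means.reindex(exp.index)
        else:
            cfg = self.model.config
            geno = self.effects["genotype"].reindex(exp["genotype"]).to_numpy()
            treat = self.effects["treatment"].reindex(exp["treatment"]).to_numpy()
            rep = self.effects["replicate"].reindex(exp["replicate"]).to_numpy()
            phi = self.effects["plot"].reindex(exp.index).to_numpy()
            est = self.grand_mean + geno + treat + rep + phi
            if cfg.include_interaction:
                key = exp["genotype"].astype(str) + ":" + exp["treatment"].astype(str)
                est = est + self.effects["interaction"].reindex(key).fillna(0.0).to_numpy()
            if cfg.include_treatment_by_replicate:
                key = exp["treatment"].astype(str) + "|" + exp["replicate"].astype(str)
                est = est + self.effects["treatment_by_replicate"].reindex(key).fillna(0.0).to_numpy()
            if level == "t_c":
                est = est + self.effects["spatial"].reindex(exp.index).to_numpy()
            if level == "t_defl":
                est = est - self.effects["treatment"].reindex(exp["treatment"]).to_numpy()
            est = pd.Series(est, index=exp.index)

        out = pd.DataFrame({"plot_id": est.index, "estimate_K": est.to_numpy()})
        out["level"] = level
        return out.reset_index(drop=True)

    def spatial_trend(self) -> pd.DataFrame:
        """Plot-wise spatial trend: exactly t_c - ts_c (the spatial BLUP)."""
        tc = self.predict("t_c").set_index("plot_id")["estimate_K"]
        tsc = self.predict("ts_c").set_index("plot_id")["estimate_K"]
        trend = tc - tsc
        return pd.DataFrame({"plot_id": trend.index, "trend_K": trend.to_numpy()})

    def row_col_effects(self):
        """Marginal row/column means and the doubly-centred 2-D surface."""
        meta = self.model.layout.plots.set_index("plot_id")
        sp = self.effects["spatial"]
        rows = meta.loc[sp.index, "row"]
        cols = meta.loc[sp.index, "col"]
        row_eff = sp.groupby(rows.to_numpy()).mean()
        col_eff = sp.groupby(cols.to_numpy()).mean()
        surface = sp - row_eff.reindex(rows).to_numpy() - col_eff.reindex(cols).to_numpy() + sp.mean()
        return row_eff, col_eff, surface

    def variance_table(self) -> pd.DataFrame:
        """Sample variance of the plot estimates at every correction level."""
        recs = []
        for level in PREDICTION_LEVELS:
            est = self.predict(level)["estimate_K"]
            recs.append({"level": level, "variance_K2": float(est.var(ddof=1))})
        return pd.DataFrame(recs)

    def summary(self) -> str:
        lines = [
            "Stage-1 canopy-temperature decomposition",
            f"  records: {len(self.residuals)}  plots: {len(self.effects['plot'])}"
            f"  flights: {len(self.flight_offsets)}",
            f"  converged in {self.n_iter} sweeps (last delta {self.last_delta:.2e} K)",
            f"  grand mean: {self.grand_mean:.3f} K",
            "  variance components (K^2):",
        ]
        for k, v in self.variance_components.items():
            lines.append(f"    {k:<10s} {v:10.5f}")
        lines.append(
            f"  spatial AR(1) correlations: row {self.spatial_rho[0]:.3f}, "
            f"col {self.spatial_rho[1]:.3f}"
        )
        for level in PREDICTION_LEVELS:
            v = float(self.predict(level)["estimate_K"].var(ddof=1))
            lines.append(f"  var(theta_{level:<6s}) = {v:.4f} K^2")
        return "\n".join(lines)

    def effects_frame(self) -> pd.DataFrame:
        """Tidy (family, level, estimate_K) export of all effect estimates."""
        rows = [("grand_mean", "", self.grand_mean)]
        for fam, s in self.effects.items():
            rows += [(fam, str(k), float(v)) for k, v in s.items()]
        return pd.DataFrame(rows, columns=["family", "level", "estimate_K"])


# ---------------------------------------------------------------------------
# module-level operation wrappers
# ---------------------------------------------------------------------------

def fit_stage1(measurements, layout, config: Stage1Config | None = None) -> Stage1Results:
    """Fit the stage-1 decomposition (see :class:`CanopyTemperatureModel`)."""
    return CanopyTemperatureModel(measurements, layout, config).fit()


def predict(fit: Stage1Results, level: str, measurements=None) -> pd.DataFrame:
    return fit.predict(level)


def spatial_trend(fit: Stage1Results, measurements=None, flights: str = "single") -> pd.DataFrame:
    """Spatial trend from a fitted model.

    ``flights="campaign"`` expects ``fit`` to be a pooled fit over the
    campaign's flights (the trend is shared); ``"single"`` a one-flight fit.
    """
    if flights == "campaign" and len(fit.flight_offsets) < 2:
        raise ValueError("campaign mode requires a fit pooled over >= 2 flights")
    return fit.spatial_trend()


def variance_table(estimate_sets: pd.DataFrame) -> pd.DataFrame:
    """Variance of plot estimates per flight x correction level.

    ``estimate_sets`` is a long DataFrame with columns flight_id, level,
    estimate_K (one row per plot).
    """
    if estimate_sets.groupby(["flight_id", "level"]).size().min() < 2:
        raise ValueError("need >= 2 plots per flight x level")
    out = (
        estimate_sets.groupby(["flight_id", "level"])["estimate_K"]
        .var(ddof=1)
        .rename("variance_K2")
        .reset_index()
    )
    return out


def repeatability(plot_values: pd.Series, layout, n_rep: int | None = None) -> float:
    """Intraclass repeatability of plot values grouped by genotype.

    Plot values are first adjusted for replicate means and linear row/column
    trends, then genotypic and residual variance are separated by one-way
    random-effect moments: sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_rep),
    clipped to [0, 1].  Requires >= 2 replicates per genotype.
    """
    meta = layout.plots.set_index("plot_id")
    meta = meta.loc[plot_values.index]
    exp = ~meta["is_border"]
    v = plot_values[exp].to_numpy(dtype=float)
    geno = meta.loc[exp, "genotype"].to_numpy()
    repl = meta.loc[exp, "replicate"].to_numpy()
    rows = meta.loc[exp, "row"].to_numpy(dtype=float)
    cols = meta.loc[exp, "col"].to_numpy(dtype=float)

    counts = pd.Series(geno).value_counts()
    if n_rep is None:
        n_rep = int(round(counts.mean()))
    if counts.min() < 2:
        raise ValueError("repeatability undefined with a single replicate per genotype")

    # adjust for replicate + linear row/col trends
    rep_levels, rep_code = np.unique(repl, return_inverse=True)
    X = np.column_stack(
        [np.eye(len(rep_levels))[rep_code], rows - rows.mean(), cols - cols.mean()]
    )
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    adj = v - X @ beta
    adj = adj - adj.mean()

    df_g = pd.DataFrame({"g": geno, "v": adj})
    group_means = df_g.groupby("g")["v"].mean()
    k = df_g.groupby("g").size()
    n = len(adj)
    a = len(group_means)
    if a < 2 or n <= a:
        return 0.0
    ss_b = float((k * (group_means - adj.mean()) ** 2).sum())
    ss_w = float(((df_g["v"] - group_means.reindex(df_g["g"]).to_numpy()) ** 2).sum())
    ms_b = ss_b / (a - 1)
    ms_w = ss_w / (n - a)
    n0 = (n - float((k**2).sum()) / n) / (a - 1)
    sigma_g2 = max((ms_b - ms_w) / n0, 0.0)
    sigma_e2 = ms_w
    if sigma_g2 + sigma_e2 <= 0:
        return 0.0
    rep_val = sigma_g2 / (sigma_g2 + sigma_e2 / n_rep)
    return float(min(max(rep_val, 0.0), 1.0))
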