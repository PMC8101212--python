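"""Summary statistics, reference-table construction and likelihood-free
(ABC) demographic model choice and parameter estimation.

Model choice follows the rejection + discriminant pipeline: statistics are
standardised, the closest fraction of simulations is retained, statistics
are logit-transformed, projected on linear discriminant axes, and a
locally-weighted (Epanechnikov) multinomial logistic regression evaluated at
the observed point yields model posterior probabilities with delta-method
confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coalescent import MutationModel, ParamDraw, Scenario, Uniform, sample_priors, simulate_dataset
from .stats import _unbiased_he, _wc_components_locus
from .types import GenotypeMatrix, LocusDef, ValidationError, spawn_rng

__all__ = [
    "SummaryStatVector",
    "ReferenceTable",
    "ModelPosterior",
    "ParameterPosterior",
    "summary_statistics",
    "build_reference_table",
    "abc_model_choice",
    "abc_parameter_posterior",
]


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStatVector:
    names: list[str]
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def _group_arrays(gm: GenotypeMatrix, group_rows: Sequence[np.ndarray]):
    """Per (group, locus): (codes (m,2), sizes) restricted to typed calls."""
    out = []
    for rows in group_rows:
        per_locus = []
        for j in range(gm.n_loci):
            codes, sizes = gm.locus_codes(j)
            sub = codes[rows]
            sub = sub[sub[:, 0] >= 0]
            per_locus.append((sub, sizes))
        out.append(per_locus)
    return out


def _one_sample(per_locus) -> tuple[float, float, float]:
    nal, het, var = [], [], []
    for sub, sizes in per_locus:
        if len(sub) == 0:
            continue
        copies = sizes[sub.ravel()]
        uniq = np.unique(copies)
        nal.append(uniq.size)
        cnt = np.bincount(sub.ravel(), minlength=sizes.size).astype(float)
        p = cnt / cnt.sum()
        het.append(_unbiased_he(p[p > 0], cnt.sum()))
        var.append(float(np.var(copies, ddof=1)) if copies.size > 1 else 0.0)
    return float(np.mean(nal)), float(np.mean(het)), float(np.mean(var))


def _dosage_small(sub: np.ndarray, A: int) -> np.ndarray:
    D = np.zeros((len(sub), A))
    np.add.at(D, (np.arange(len(sub)), sub[:, 0]), 1.0)
    np.add.at(D, (np.arange(len(sub)), sub[:, 1]), 1.0)
    return D


def summary_statistics(
    gm: GenotypeMatrix, groups: Mapping[str, Sequence[int]] | None = None
) -> SummaryStatVector:
    """One- and two-sample microsatellite summary statistics.

    One-sample per group: mean number of alleles (NAL), mean unbiased
    genetic diversity (HET), mean allele-size variance (VAR).  Two-sample
    per ordered group pair: pooled NAL/HET/VAR, shared-allele distance DAS,
    classification indices LIK in both directions (Laplace-smoothed),
    Weir–Cockerham FST and Goldstein's (delta-mu)^2.
    """
    if groups is None:
        idx = gm.population_indices()
    else:
        idx = {k: np.asarray(v, dtype=np.intp) for k, v in groups.items()}
    labels = list(idx)
    if not labels:
        raise ValidationError("at least one group required")
    for lab, rows in idx.items():
        if len(rows) == 0:
            raise ValidationError(f"group {lab!r} is empty")
    rows_list = [idx[lab] for lab in labels]
    arrays = _group_arrays(gm, rows_list)
    names: list[str] = []
    vals: list[float] = []
    for lab, per_locus in zip(labels, arrays):
        nal, het, var = _one_sample(per_locus)
        names += [f"NAL_{lab}", f"HET_{lab}", f"VAR_{lab}"]
        vals += [nal, het, var]
    for gi in range(len(labels)):
        for gj in range(gi + 1, len(labels)):
            la, lb = labels[gi], labels[gj]
            pooled = [
                (np.vstack([arrays[gi][j][0], arrays[gj][j][0]]), arrays[gi][j][1])
                for j in range(gm.n_loci)
            ]
            nal, het, var = _one_sample(pooled)
            das = _shared_allele_distance(arrays[gi], arrays[gj])
            lik_ab = _classification_index(arrays[gi], arrays[gj])
            lik_ba = _classification_index(arrays[gj], arrays[gi])
            fst = _pair_fst(gm, rows_list[gi], rows_list[gj])
            dmu2 = _goldstein_d(arrays[gi], arrays[gj])
            names += [
                f"NAL_{la}_{lb}", f"HET_{la}_{lb}", f"VAR_{la}_{lb}",
                f"DAS_{la}_{lb}", f"LIK_{la}to{lb}", f"LIK_{lb}to{la}",
                f"FST_{la}_{lb}", f"DMU2_{la}_{lb}",
            ]
            vals += [nal, het, var, das, lik_ab, lik_ba, fst, dmu2]
    return SummaryStatVector(names, np.asarray(vals, dtype=float))


def _shared_allele_distance(a, b) -> float:
    """1 - mean proportion of alleles shared between cross-group individual
    pairs, averaged over loci."""
    per_locus = []
    for (sa, sizes), (sb, _) in zip(a, b):
        if len(sa) == 0 or len(sb) == 0:
            continue
        A = sizes.size
        Da = _dosage_small(sa, A)
        Db = _dosage_small(sb, A)
        shared = np.minimum(Da[:, None, :], Db[None, :, :]).sum(axis=2) / 2.0
        per_locus.append(float(shared.mean()))
    if not per_locus:
        return np.nan
    return 1.0 - float(np.mean(per_locus))


def _classification_index(src, ref) -> float:
    """Mean over source individuals of the log-likelihood of their genotype
    under the reference group's allele frequencies (add-one smoothing)."""
    total = None
    for (ss, sizes), (sr, _) in zip(src, ref):
        if len(ss) == 0:
            continue
        A = sizes.size
        cnt = np.bincount(sr.ravel(), minlength=A).astype(float) + 1.0
        f = cnt / cnt.sum()
        logf = np.log(f)
        het = ss[:, 0] != ss[:, 1]
        ll = logf[ss[:, 0]] + logf[ss[:, 1]] + het * np.log(2.0)
        total = ll if total is None else total + ll
    return float(np.mean(total)) if total is not None else np.nan


def _pair_fst(gm: GenotypeMatrix, rows_a: np.ndarray, rows_b: np.ndarray) -> float:
    num = den = 0.0
    for j in range(gm.n_loci):
        codes, _ = gm.locus_codes(j)
        a, b, c = _wc_components_locus(codes, [rows_a, rows_b])
        num += a
        den += a + b + c
    return num / den if den != 0 else np.nan


def _goldstein_d(a, b) -> float:
    d2 = []
    for (sa, sizes), (sb, _) in zip(a, b):
        if len(sa) == 0 or len(sb) == 0:
            continue
        ma = float(np.mean(sizes[sa.ravel()]))
        mb = float(np.mean(sizes[sb.ravel()]))
        d2.append((ma - mb) ** 2)
    return float(np.mean(d2)) if d2 else np.nan


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    models: list[str]
    model_ids: np.ndarray
    stats: np.ndarray
    stat_names: list[str]
    params: pd.DataFrame
    param_bounds: dict[str, tuple[float, float]]
    n_per_model: int
    scaled_down: bool = True
    standardise_mean: np.ndarray = field(default=None)
    standardise_sd: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.standardise_mean is None:
            self.standardise_mean = np.nanmean(self.stats, axis=0)
            sd = np.nanstd(self.stats, axis=0)
            sd[sd == 0] = 1.0
            self.standardise_sd = sd

    def standardised(self) -> np.ndarray:
        return (self.stats - self.standardise_mean) / self.standardise_sd

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        header = {
            "models": self.models,
            "stat_names": self.stat_names,
            "param_bounds": {k: list(v) for k, v in self.param_bounds.items()},
            "n_per_model": self.n_per_model,
            "scaled_down": self.scaled_down,
            "standardise_mean": self.standardise_mean.tolist(),
            "standardise_sd": self.standardise_sd.tolist(),
        }
        df = pd.DataFrame(self.stats, columns=self.stat_names)
        df.insert(0, "model", [self.models[i] for i in self.model_ids])
        df = pd.concat([df, self.params.reset_index(drop=True)], axis=1)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            df.to_csv(fh, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceTable":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline().lstrip("#"))
            df = pd.read_csv(fh)
        models = header["models"]
        stat_names = header["stat_names"]
        model_ids = np.asarray([models.index(m) for m in df["model"]])
        stats = df[stat_names].to_numpy(float)
        params = df.drop(columns=["model", *stat_names])
        return cls(
            models=models,
            model_ids=model_ids,
            stats=stats,
            stat_names=stat_names,
            params=params,
            param_bounds={k: tuple(v) for k, v in header["param_bounds"].items()},
            n_per_model=header["n_per_model"],
            scaled_down=header["scaled_down"],
            standardise_mean=np.asarray(header["standardise_mean"]),
            standardise_sd=np.asarray(header["standardise_sd"]),
        )


def _prior_bounds(scenario: Scenario, model: MutationModel) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for name, size in scenario.populations.items():
        if isinstance(size, Uniform):
            out[f"N_{name}"] = (size.lo, size.hi)
    for i, e in enumerate(scenario.events):
        if isinstance(e.time, Uniform):
            out[f"t_{i}"] = (e.time.lo, e.time.hi)
        if e.kind == "admix" and isinstance(e.rate, Uniform):
            out[f"r_{i}"] = (e.rate.lo, e.rate.hi)
        if e.kind == "size_change" and isinstance(e.size, Uniform):
            out[f"size_{i}"] = (e.size.lo, e.size.hi)
    for attr, key in (("mu_mean", "mu_mean"), ("p_geom", "P"), ("mu_sni", "mu_sni")):
        v = getattr(model, attr)
        if isinstance(v, Uniform):
            out[key] = (v.lo, v.hi)
    return out


def build_reference_table(
    scenarios: Sequence[Scenario],
    model: MutationModel,
    loci: Sequence[LocusDef],
    n_sims: int,
    seed: int | None = None,
    max_retries: int = 10,
) -> ReferenceTable:
    """Simulate ``n_sims`` datasets per scenario and collect summary stats.

    Failed simulations are retried with a fresh sub-seed (logged via the
    retry counter embedded in the row order being deterministic per seed).
    """
    rows = []
    model_ids = []
    param_rows = []
    stat_names: list[str] | None = None
    bounds: dict[str, tuple[float, float]] = {}
    for s_idx, scen in enumerate(scenarios):
        scen.validate()
        bounds.update(_prior_bounds(scen, model))
        rng = spawn_rng(seed, "reftable", scen.name)
        groups_order = [p for p, k in scen.samples.items() if k > 0]
        for _ in range(n_sims):
            for attempt in range(max_retries):
                try:
                    gm, draw = simulate_dataset(scen, model, loci, rng=rng)
                    groups = gm.population_indices()
                    sv = summary_statistics(gm, {g: groups[g] for g in groups_order})
                    break
                except ValidationError:
                    if attempt == max_retries - 1:
                        raise
            if stat_names is None:
                stat_names = [n.replace(scen.name + "_", "") for n in sv.names]
            rows.append(sv.values)
            model_ids.append(s_idx)
            param_rows.append(draw.values)
    stats = np.vstack(rows)
    if not np.isfinite(stats).all():
        stats = np.nan_to_num(stats, nan=0.0)
    return ReferenceTable(
        models=[s.name for s in scenarios],
        model_ids=np.asarray(model_ids),
        stats=stats,
        stat_names=list(stat_names),
        params=pd.DataFrame(param_rows),
        param_bounds=bounds,
        n_per_model=n_sims,
    )


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------


@dataclass
class ModelPosterior:
    models: list[str]
    probabilities: np.ndarray
    ci: np.ndarray  # (n_models, 2)
    retained: int
    best: str
    significant: bool
    lda_axes: int
    rejection_probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.models,
                "posterior": self.probabilities,
                "ci_low": self.ci[:, 0],
                "ci_high": self.ci[:, 1],
                "rejection": self.rejection_probabilities,
            }
        )


def _logit_map(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = np.where(hi > lo, hi - lo, 1.0)
    u = np.clip((x - lo) / span, 1e-6, 1 - 1e-6)
    return np.log(u / (1 - u))


def _wmultinom_fit(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, n_classes: int,
    max_iter: int = 100, ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted multinomial logistic regression by Newton's method.

    Returns coefficient matrix B ((n_classes-1) x (d+1), last class as
    reference) and the inverse Hessian (asymptotic covariance of vec(B)).
    """
    n, d = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    p = d + 1
    C = n_classes
    B = np.zeros((C - 1, p))
    Y = np.zeros((n, C))
    Y[np.arange(n), y] = 1.0
    for _ in range(max_iter):
        eta = Xd @ B.T
        eta = np.hstack([eta, np.zeros((n, 1))])
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        G = np.empty((C - 1, p))
        for c in range(C - 1):
            G[c] = Xd.T @ (w * (Y[:, c] - P[:, c]))
        H = np.empty(((C - 1) * p, (C - 1) * p))
        for c1 in range(C - 1):
            for c2 in range(C - 1):
                wcc = w * P[:, c1] * ((c1 == c2) - P[:, c2])
                H[c1 * p:(c1 + 1) * p, c2 * p:(c2 + 1) * p] = Xd.T @ (wcc[:, None] * Xd)
        H += ridge * np.eye(H.shape[0])
        step = np.linalg.solve(H, G.ravel())
        B_new = B + step.reshape(C - 1, p)
        if np.max(np.abs(B_new - B)) < 1e-8:
            B = B_new
            break
        B = B_new
    cov = np.linalg.inv(H)
    return B, cov


def _predict_with_ci(B: np.ndarray, cov: np.ndarray, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    C = B.shape[0] + 1
    p = B.shape[1]
    xd = np.concatenate([[1.0], x0])
    eta = np.concatenate([B @ xd, [0.0]])
    eta -= eta.max()
    probs = np.exp(eta)
    probs /= probs.sum()
    ci = np.empty((C, 2))
    # delta method: d p_c / d B_{k,j} = p_c (delta_ck - p_k) x_j
    for c in range(C):
        grad = np.empty((C - 1) * p)
        for k in range(C - 1):
            grad[k * p:(k + 1) * p] = probs[c] * ((c == k) - probs[k]) * xd
        var = float(grad @ cov @ grad)
        half = 1.96 * np.sqrt(max(var, 0.0))
        ci[c] = (max(0.0, probs[c] - half), min(1.0, probs[c] + half))
    return probs, ci


def abc_model_choice(
    ref: ReferenceTable,
    observed: SummaryStatVector | np.ndarray,
    retain: float = 0.01,
    min_retained: int = 100,
) -> ModelPosterior:
    """Rejection + LDA + weighted multinomial logistic model posteriors.

    The best model is flagged significant when its 95% CI does not overlap
    the second-best model's.
    """
    obs = observed.values if isinstance(observed, SummaryStatVector) else np.asarray(observed)
    if len(ref.models) < 2:
        raise ValidationError("model choice needs at least 2 models")
    Z = ref.standardised()
    z_obs = (obs - ref.standardise_mean) / ref.standardise_sd
    d2 = np.sum((Z - z_obs[None, :]) ** 2, axis=1)
    n_keep = max(int(np.ceil(retain * len(d2))), min(min_retained, len(d2)))
    keep = np.argsort(d2)[:n_keep]
    dmax = np.sqrt(d2[keep].max()) or 1.0
    w = 1.0 - (np.sqrt(d2[keep]) / dmax) ** 2
    w = np.clip(w, 1e-8, None)
    y = ref.model_ids[keep]
    rej = np.bincount(y, minlength=len(ref.models)) / n_keep

    # logit transform on pooled min/max, then LDA
    lo = np.nanmin(ref.stats, axis=0)
    hi = np.nanmax(ref.stats, axis=0)
    Xl = _logit_map(ref.stats[keep], lo, hi)
    x_obs = _logit_map(obs[None, :], lo, hi)[0]
    span_ok = hi > lo
    Xl = Xl[:, span_ok]
    x_obs = x_obs[span_ok]

    n_classes = len(ref.models)
    lda_axes = 0
    present = np.unique(y)
    if present.size < 2:
        probs = np.zeros(n_classes)
        probs[present[0]] = 1.0
        ci = np.tile(probs[:, None], (1, 2))
        return ModelPosterior(ref.models, probs, ci, n_keep, ref.models[present[0]],
                              True, 0, rej)
    try:
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        n_comp = min(present.size - 1, Xl.shape[1])
        lda = LinearDiscriminantAnalysis(n_components=n_comp)
        Xp = lda.fit_transform(Xl, y)
        xp_obs = lda.transform(x_obs[None, :])[0]
        lda_axes = n_comp
    except Exception:
        Xp, xp_obs = Xl, x_obs  # degenerate LDA: fall back to logit stats
    # map class labels to compact range for the fit
    remap = {c: i for i, c in enumerate(present)}
    y_c = np.asarray([remap[v] for v in y])
    B, cov = _wmultinom_fit(Xp, y_c, w, present.size)
    probs_c, ci_c = _predict_with_ci(B, cov, xp_obs)
    probs = np.zeros(n_classes)
    ci = np.zeros((n_classes, 2))
    for c, i in remap.items():
        probs[c] = probs_c[i]
        ci[c] = ci_c[i]
    order = np.argsort(probs)[::-1]
    best, second = order[0], order[1]
    significant = bool(ci[best, 0] > ci[second, 1])
    return ModelPosterior(
        models=list(ref.models),
        probabilities=probs,
        ci=ci,
        retained=n_keep,
        best=ref.models[best],
        significant=significant,
        lda_axes=lda_axes,
        rejection_probabilities=rej,
    )


# ---------------------------------------------------------------------------
# Parameter posterior
# ---------------------------------------------------------------------------


@dataclass
class ParameterPosterior:
    model: str
    samples: pd.DataFrame
    weights: np.ndarray
    quantiles: pd.DataFrame


def _weighted_quantiles(x: np.ndarray, w: np.ndarray, qs: Sequence[float]) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    cw /= cw[-1]
    return np.interp(qs, cw, xs)


def abc_parameter_posterior(
    ref: ReferenceTable,
    model: str,
    observed: SummaryStatVector | np.ndarray,
    retain: float = 0.01,
    ridge: float = 1e-6,
) -> ParameterPosterior:
    """Local-linear regression-adjusted posterior for one model's parameters.

    Parameters with declared prior bounds are logit-mapped before the
    weighted linear adjustment so adjusted draws respect the prior support.
    """
    obs = observed.values if isinstance(observed, SummaryStatVector) else np.asarray(observed)
    sel = ref.model_ids == ref.models.index(model)
    Z = ref.standardised()[sel]
    z_obs = (obs - ref.standardise_mean) / ref.standardise_sd
    d2 = np.sum((Z - z_obs[None, :]) ** 2, axis=1)
    n_keep = max(int(np.ceil(retain * len(d2))), min(100, len(d2)))
    keep = np.argsort(d2)[:n_keep]
    dmax = np.sqrt(d2[keep].max()) or 1.0
    w = np.clip(1.0 - (np.sqrt(d2[keep]) / dmax) ** 2, 1e-8, None)
    S = Z[keep]
    params = ref.params.loc[np.where(sel)[0][keep]].reset_index(drop=True)

    adj = {}
    sw = np.sqrt(w)
    X = np.hstack([np.ones((n_keep, 1)), S - z_obs[None, :]])
    Xw = X * sw[:, None]
    XtX = Xw.T @ Xw + ridge * np.eye(X.shape[1])
    for col in params.columns:
        theta = params[col].to_numpy(float)
        bounds = ref.param_bounds.get(col)
        if bounds is not None and bounds[1] > bounds[0]:
            lo, hi = bounds
            t = _logit_map(theta, np.full_like(theta, lo), np.full_like(theta, hi))
        else:
            t = theta
            lo = hi = None
        beta = np.linalg.solve(XtX, Xw.T @ (t * sw))
        t_adj = t - (X[:, 1:] @ beta[1:])
        if lo is not None:
            u = 1.0 / (1.0 + np.exp(-t_adj))
            t_adj = lo + u * (hi - lo)
        adj[col] = t_adj
    samples = pd.DataFrame(adj)
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    qrows = {
        col: _weighted_quantiles(samples[col].to_numpy(), w, qs) for col in samples.columns
    }
    quantiles = pd.DataFrame(qrows, index=[f"q{int(q * 1000) / 10}" for q in qs]).T
    return ParameterPosterior(model=model, samples=samples, weights=w, quantiles=quantiles)
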