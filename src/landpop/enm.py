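"""Environmental niche suitability modelling and evaluation.

Suitability in [0, 1] is modelled with an L1-penalized logistic
presence/background classifier on standardized linear and quadratic terms
of the four bioclimatic layers — the penalized-GLM formulation of
maximum-entropy niche modelling. Evaluation uses AUC (rank statistic of
presence versus background scores), the true skill statistic (TSS), and
fourfold spatial-block cross-validation; the multivariate environmental
similarity surface (MESS) flags extrapolation when projecting to past
climates, and habitat stability is the cellwise mean suitability across
epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .raster import Raster, require_aligned

__all__ = [
    "SuitabilityModel",
    "EvaluationReport",
    "fit_suitability",
    "predict_suitability",
    "evaluate",
    "spatial_block_cv",
    "mess",
    "habitat_stability",
]

BIOCLIM_ORDER = ("bio1", "bio2", "bio12", "bio15")


@dataclass
class SuitabilityModel:
    layer_names: tuple[str, ...]
    feature_means: np.ndarray      # standardization of linear terms
    feature_sds: np.ndarray
    coefficients: np.ndarray       # (n_replicates, 2 * n_layers) for [x, x^2]
    intercepts: np.ndarray         # (n_replicates,)
    regularization_c: float
    n_presences: int
    n_background: int
    seed: int

    def features(self, layer_values: np.ndarray) -> np.ndarray:
        """Standardized [x, x^2] design from raw layer values (n, n_layers)."""
        z = (layer_values - self.feature_means) / self.feature_sds
        return np.hstack([z, z**2])

    def predict(self, layer_values: np.ndarray) -> np.ndarray:
        """Mean replicate probability for raw layer values (n, n_layers)."""
        x = self.features(layer_values)
        eta = x @ self.coefficients.T + self.intercepts[None, :]
        return (1.0 / (1.0 + np.exp(-eta))).mean(axis=1)


@dataclass
class EvaluationReport:
    auc: float
    tss: float
    tss_threshold: float
    per_fold: list = field(default_factory=list)


def _extract_layer_values(bioclim: dict[str, Raster], lons: np.ndarray,
                          lats: np.ndarray) -> np.ndarray:
    layers = [bioclim[n] for n in BIOCLIM_ORDER if n in bioclim]
    if len(layers) != len(bioclim):
        layers = list(bioclim.values())
    require_aligned(*layers)
    ref = layers[0]
    rows = np.floor((ref.north - lats) / ref.cell_size).astype(int)
    cols = np.floor((lons - ref.west) / ref.cell_size).astype(int)
    rows = np.clip(rows, 0, ref.shape[0] - 1)
    cols = np.clip(cols, 0, ref.shape[1] - 1)
    return np.column_stack([lay.values[rows, cols] for lay in layers])


def fit_suitability(
    presences: np.ndarray,
    bioclim: dict[str, Raster],
    n_background: int = 10000,
    train_frac: float = 0.8,
    reps: int = 10,
    seed: int = 0,
    regularization_c: float = 1.0,
    max_iter: int = 500,
) -> tuple[SuitabilityModel, EvaluationReport]:
    """Fit the presence/background suitability model.

    Per replicate a random 80/20 presence split trains the penalized
    classifier; the model stores all replicate coefficient vectors and
    predicts with their mean probability. Background points are sampled
    from non-presence, non-nodata cells. Returns the averaged model and an
    evaluation report on the held-out presences (AUC/TSS averaged over
    replicates).
    """
    presences = np.asarray(presences, dtype=float)
    if presences.shape[0] < 20:
        raise ValueError("need at least 20 presence points")
    names = tuple(bioclim.keys())
    layers = list(bioclim.values())
    require_aligned(*layers)
    ref = layers[0]
    rng = np.random.default_rng(seed)

    occupied = np.zeros(ref.shape, dtype=bool)
    for lon, lat in presences:
        try:
            r, c = ref.index_of(lon, lat)
        except ValueError:
            continue
        occupied[r, c] = True
    candidates = np.argwhere(~ref.nodata_mask & ~occupied)
    if candidates.shape[0] == 0:
        raise ValueError("no background cells available")
    take = min(n_background, candidates.shape[0])
    bg_idx = candidates[rng.choice(candidates.shape[0], size=take, replace=n_background > candidates.shape[0])]
    bg_lon = ref.west + (bg_idx[:, 1] + 0.5) * ref.cell_size
    bg_lat = ref.north - (bg_idx[:, 0] + 0.5) * ref.cell_size

    x_pres = _extract_layer_values(bioclim, presences[:, 0], presences[:, 1])
    x_bg = _extract_layer_values(bioclim, bg_lon, bg_lat)
    all_x = np.vstack([x_pres, x_bg])
    sds = all_x.std(axis=0)
    keep = sds > 0
    if not keep.all():
        warnings.warn(f"dropping zero-variance layers {np.asarray(names)[~keep]}")
    if not keep.any():
        raise ValueError("all layers have zero variance")
    means = all_x.mean(axis=0)
    sds = np.where(keep, sds, 1.0)

    model = SuitabilityModel(
        names, means, sds, np.zeros((reps, 2 * len(names))), np.zeros(reps),
        regularization_c, presences.shape[0], take, seed,
    )
    aucs, tsss, fold_rows = [], [], []
    n_pres = x_pres.shape[0]
    for rep in range(reps):
        order = rng.permutation(n_pres)
        n_train = max(int(round(train_frac * n_pres)), 1)
        tr, te = order[:n_train], order[n_train:]
        X = model.features(np.vstack([x_pres[tr], x_bg]))
        X[:, np.concatenate([~keep, ~keep])] = 0.0
        y = np.concatenate([np.ones(len(tr)), np.zeros(x_bg.shape[0])])
        clf = LogisticRegression(
            l1_ratio=1, C=regularization_c, solver="liblinear",
            max_iter=max_iter, random_state=int(rng.integers(2**31 - 1)),
        )
        clf.fit(X, y)
        model.coefficients[rep] = clf.coef_[0]
        model.intercepts[rep] = clf.intercept_[0]
        if len(te) >= 5:
            scores_p = model.predict(x_pres[te])
            scores_b = model.predict(x_bg)
            rep_eval = evaluate_scores(scores_p, scores_b)
            aucs.append(rep_eval.auc)
            tsss.append(rep_eval.tss)
            fold_rows.append({"replicate": rep, "auc": rep_eval.auc, "tss": rep_eval.tss})
    report = EvaluationReport(
        float(np.mean(aucs)) if aucs else float("nan"),
        float(np.mean(tsss)) if tsss else float("nan"),
        float("nan"), fold_rows,
    )
    return model, report


def predict_suitability(model: SuitabilityModel, bioclim: dict[str, Raster]) -> Raster:
    """Cellwise suitability raster; nodata propagates from the input layers."""
    missing = [n for n in model.layer_names if n not in bioclim]
    if missing:
        raise ValueError(f"missing layers for prediction: {missing}")
    layers = [bioclim[n] for n in model.layer_names]
    require_aligned(*layers)
    ref = layers[0]
    stack = np.stack([lay.values for lay in layers], axis=-1)
    mask = np.zeros(ref.shape, dtype=bool)
    for lay in layers:
        mask |= lay.nodata_mask
    flat = stack.reshape(-1, len(layers))
    out = np.full(flat.shape[0], np.nan)
    ok = ~mask.ravel()
    out[ok] = model.predict(np.nan_to_num(flat[ok]))
    return ref.with_values(out.reshape(ref.shape), "suitability")


def evaluate_scores(presence_scores: np.ndarray, background_scores: np.ndarray) -> EvaluationReport:
    """AUC (Mann–Whitney rank statistic, ties count half) and maximized TSS."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if b.size == 0:
        raise ValueError("no background scores")
    ranks = rankdata(np.concatenate([p, b]))
    auc = (ranks[: p.size].sum() - p.size * (p.size + 1) / 2) / (p.size * b.size)
    thresholds = np.unique(np.concatenate([p, b]))
    best_tss, best_thr = -1.0, thresholds[0]
    for thr in thresholds:
        sens = (p >= thr).mean()
        spec = (b < thr).mean()
        tss = sens + spec - 1
        if tss > best_tss:
            best_tss, best_thr = tss, thr
    return EvaluationReport(float(auc), float(best_tss), float(best_thr))


def evaluate(
    model: SuitabilityModel,
    test_presences: np.ndarray,
    bioclim: dict[str, Raster],
    background: np.ndarray,
) -> EvaluationReport:
    """Score held-out presences and background points through the model."""
    test_presences = np.asarray(test_presences, dtype=float)
    if test_presences.shape[0] < 5:
        raise ValueError("need at least 5 test presences")
    xp = _extract_layer_values(dict(zip(model.layer_names, (bioclim[n] for n in model.layer_names))),
                               test_presences[:, 0], test_presences[:, 1])
    xb = _extract_layer_values(dict(zip(model.layer_names, (bioclim[n] for n in model.layer_names))),
                               np.asarray(background)[:, 0], np.asarray(background)[:, 1])
    return evaluate_scores(model.predict(xp), model.predict(xb))


def spatial_block_cv(
    presences: np.ndarray,
    extent: tuple[float, float, float, float],
    k: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Assign each point to one of 4 contiguous rectangular blocks (2x2 split).

    A point exactly on an internal boundary belongs to the block on its
    south/west side. Returns the fold index per point (0..3).
    """
    if k != 4:
        raise ValueError("spatial block CV uses a fixed 2x2 split (k=4)")
    pts = np.asarray(presences, dtype=float)
    west, south, east, north = extent
    mid_lon = (west + east) / 2
    mid_lat = (south + north) / 2
    east_half = pts[:, 0] > mid_lon       # boundary goes to the west block
    north_half = pts[:, 1] > mid_lat      # boundary goes to the south block
    folds = east_half.astype(int) + 2 * north_half.astype(int)
    occupied = np.unique(folds)
    if occupied.size < 2:
        raise ValueError("presences occupy fewer than 2 spatial blocks")
    if occupied.size < 4:
        warnings.warn(f"only {occupied.size} of 4 blocks hold presences; empty folds skipped")
    return folds


def mess(reference: dict[str, np.ndarray], target: dict[str, Raster]) -> Raster:
    """Multivariate environmental similarity surface.

    Per cell and variable, with f the percentage of reference values
    strictly below the cell value v and [mn, mx] the reference range:
    f=0 -> 100 (v-mn)/(mx-mn); 0<f<=50 -> 2f; 50<f<100 -> 2(100-f);
    f=100 -> 100 (mx-v)/(mx-mn). The cell MESS is the minimum over
    variables; negative values flag extrapolation beyond the reference.
    """
    layers = list(target.values())
    require_aligned(*layers)
    ref_raster = layers[0]
    sims = []
    for name, raster in target.items():
        ref_vals = np.sort(np.asarray(reference[name], dtype=float))
        if ref_vals.size < 2:
            raise ValueError(f"variable {name}: need >= 2 reference values")
        mn, mx = ref_vals[0], ref_vals[-1]
        if mx == mn:
            warnings.warn(f"variable {name} has a degenerate reference range; skipped")
            continue
        v = raster.values
        f = 100.0 * np.searchsorted(ref_vals, v.ravel(), side="left") / ref_vals.size
        f = f.reshape(v.shape)
        sim = np.where(
            f == 0, 100.0 * (v - mn) / (mx - mn),
            np.where(f <= 50, 2 * f,
                     np.where(f < 100, 2 * (100 - f), 100.0 * (mx - v) / (mx - mn))),
        )
        sims.append(sim)
    if not sims:
        raise ValueError("no usable variables for MESS")
    return ref_raster.with_values(np.min(np.stack(sims), axis=0), "mess")


def habitat_stability(suitability_by_epoch: list[Raster]) -> Raster:
    """Cellwise mean suitability across epochs (1 = always suitable, 0 = never)."""
    require_aligned(*suitability_by_epoch)
    stack = np.stack([r.values for r in suitability_by_epoch])
    return suitability_by_epoch[0].with_values(np.nanmean(stack, axis=0), "stability")
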