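"""Disease-specific partial-correlation network learning.

Pipeline: z-score case profiles against a reference population; fill the
rank of the under-sampled design matrix with surrogate profiles (copies of
real samples plus standard-normal noise); estimate a sparse Gaussian Markov
Random Field by graphical lasso; convert the precision matrix to partial
correlations; and optionally prune away edges also present in a
control-only network, leaving disease-specific co-perturbation structure.

"Discriminative" designs devote half the matrix rank to disease(-surrogate)
columns and half to control(-surrogate) columns, so disease-vs-control
differences shape the learned edges.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import GraphicalLasso, empirical_covariance

from .graph import SIGNED, NodeSubset, WeightedGraph

__all__ = [
    "ProfileMatrix",
    "LearnConfig",
    "read_profiles",
    "zscore_profiles",
    "make_surrogates",
    "assemble_design",
    "learn_gmrf",
    "glasso_edge_path_scores",
    "prune_network",
    "select_perturbation_set",
    "select_features",
]

logger = logging.getLogger(__name__)

DISEASE = "disease"
CONTROL = "control"
SURROGATE_DISEASE = "surrogate_disease"
SURROGATE_CONTROL = "surrogate_control"


@dataclass(frozen=True)
class ProfileMatrix:
    """Feature-by-sample numeric matrix with per-sample class labels."""

    feature_names: tuple[str, ...]
    sample_names: tuple[str, ...]
    values: np.ndarray
    class_labels: tuple[str, ...]
    scale: str = "raw"  # raw | zscore

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "sample_names", tuple(self.sample_names))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        p, n = vals.shape
        if p != len(self.feature_names) or n != len(self.sample_names):
            raise ValueError(
                f"values shape {vals.shape} inconsistent with "
                f"{len(self.feature_names)} features x {len(self.sample_names)} samples"
            )
        if len(self.class_labels) != n:
            raise ValueError("one class label per sample required")
        if self.scale == "zscore" and not np.all(np.isfinite(vals)):
            raise ValueError("z-scored matrix contains non-finite entries")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def subset_samples(self, mask: np.ndarray | list[bool]) -> "ProfileMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ProfileMatrix(
            self.feature_names,
            tuple(np.array(self.sample_names)[mask]),
            self.values[:, mask],
            tuple(np.array(self.class_labels)[mask]),
            self.scale,
        )

    def by_class(self, *labels: str) -> "ProfileMatrix":
        mask = [c in labels for c in self.class_labels]
        return self.subset_samples(mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_names), columns=list(self.sample_names)
        )


def read_profiles(
    path: str | Path, labels_path: str | Path | None = None, sep: str | None = None
) -> ProfileMatrix:
    """Read a features-x-samples CSV/TSV (header = sample names, first
    column = feature names), optionally with a two-column sample,label file."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    labels: tuple[str, ...]
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep=sep, header=None, index_col=0)
        labels = tuple(str(lab.loc[s, 1]) for s in df.columns)
    else:
        labels = tuple("disease" for _ in df.columns)
    return ProfileMatrix(
        feature_names=tuple(str(f) for f in df.index),
        sample_names=tuple(str(s) for s in df.columns),
        values=df.to_numpy(dtype=float),
        class_labels=labels,
    )


@dataclass(frozen=True)
class LearnConfig:
    """Settings for design assembly and graphical-lasso estimation.

    ``target_rank`` is the number of columns in the assembled design
    (default: the number of features, i.e. a square design, but never
    fewer than the real samples supplied); the penalty grid is
    ``n_lambdas`` log-spaced values down to ``lambda_min_ratio`` of the
    fully-sparsifying penalty, searched by extended BIC with
    ``ebic_gamma`` trading sparsity against fit.
    """

    target_rank: int | None = None
    n_lambdas: int = 20
    lambda_min_ratio: float = 0.05
    ebic_gamma: float = 0.5
    prune: bool = True
    discriminative: bool = True
    rng_seed: int = 0


# ---------------------------------------------------------------------------
# Profile preparation
# ---------------------------------------------------------------------------

def zscore_profiles(raw: ProfileMatrix, reference: ProfileMatrix) -> ProfileMatrix:
    """Per-feature z-scores against a reference population (ddof 1).

    Features absent from the reference, with fewer than 2 reference
    observations, or with zero reference variance are dropped (logged).
    """
    ref_index = {f: i for i, f in enumerate(reference.feature_names)}
    keep: list[int] = []
    means: list[float] = []
    sds: list[float] = []
    dropped = 0
    for i, feat in enumerate(raw.feature_names):
        j = ref_index.get(feat)
        if j is None:
            dropped += 1
            continue
        ref_vals = reference.values[j]
        ref_vals = ref_vals[np.isfinite(ref_vals)]
        if ref_vals.size < 2:
            dropped += 1
            continue
        sd = float(np.std(ref_vals, ddof=1))
        if sd == 0.0:
            warnings.warn(f"zero reference variance for {feat!r}; dropped", stacklevel=2)
            dropped += 1
            continue
        keep.append(i)
        means.append(float(np.mean(ref_vals)))
        sds.append(sd)
    if dropped:
        logger.info("zscore_profiles: dropped %d feature(s) without usable reference", dropped)
    z = (raw.values[keep] - np.array(means)[:, None]) / np.array(sds)[:, None]
    return ProfileMatrix(
        feature_names=tuple(raw.feature_names[i] for i in keep),
        sample_names=raw.sample_names,
        values=z,
        class_labels=raw.class_labels,
        scale="zscore",
    )


def make_surrogates(
    profiles: ProfileMatrix, n_surrogates: int, rng_seed: int
) -> ProfileMatrix:
    """Surrogate profiles: copies of real samples plus standard-normal noise.

    Sources are cycled in column order so counts are reproducible; labels
    become the matching surrogate class.
    """
    if n_surrogates < 0:
        raise ValueError("n_surrogates must be >= 0")
    if profiles.n_samples == 0:
        raise ValueError("cannot make surrogates from an empty profile matrix")
    rng = np.random.default_rng(rng_seed)
    surro_label = {
        DISEASE: SURROGATE_DISEASE,
        CONTROL: SURROGATE_CONTROL,
        SURROGATE_DISEASE: SURROGATE_DISEASE,
        SURROGATE_CONTROL: SURROGATE_CONTROL,
    }
    cols = []
    names = []
    labels = []
    for i in range(n_surrogates):
        src = i % profiles.n_samples
        noise = rng.standard_normal(profiles.n_features)
        cols.append(profiles.values[:, src] + noise)
        names.append(f"{profiles.sample_names[src]}_surr{i:03d}")
        labels.append(surro_label.get(profiles.class_labels[src], SURROGATE_CONTROL))
    values = (
        np.column_stack(cols) if cols else np.empty((profiles.n_features, 0))
    )
    return ProfileMatrix(
        feature_names=profiles.feature_names,
        sample_names=tuple(names),
        values=values,
        class_labels=tuple(labels),
        scale=profiles.scale,
    )


def _hstack(a: ProfileMatrix, b: ProfileMatrix) -> ProfileMatrix:
    if a.feature_names != b.feature_names:
        raise ValueError("profile matrices have different feature universes")
    return ProfileMatrix(
        a.feature_names,
        a.sample_names + b.sample_names,
        np.concatenate([a.values, b.values], axis=1),
        a.class_labels + b.class_labels,
        a.scale,
    )


def assemble_design(
    disease: ProfileMatrix, control: ProfileMatrix, cfg: LearnConfig
) -> ProfileMatrix:
    """Assemble the design matrix for network learning.

    Discriminative: ceil(target_rank/2) disease-side columns (reals first,
    surrogates filling the rest) and floor(target_rank/2) control-side
    columns. Non-discriminative: all target_rank columns from the disease
    side only.
    """
    n_d, n_c = disease.n_samples, control.n_samples
    if cfg.target_rank is not None:
        target = cfg.target_rank
    else:
        # default: fill the rank of the data matrix (square design), but
        # never below the number of real samples supplied
        reals = n_d + n_c if cfg.discriminative else n_d
        target = max(disease.n_features, reals)
    if cfg.discriminative:
        if target < n_d + n_c:
            raise ValueError(
                f"target_rank {target} smaller than the {n_d + n_c} real samples"
            )
        d_side = math.ceil(target / 2)
        c_side = target - d_side
        if d_side < n_d or c_side < n_c:
            raise ValueError(
                f"half-rank split ({d_side}/{c_side}) cannot hold "
                f"{n_d} disease and {n_c} control real samples"
            )
        d_surr = make_surrogates(disease, d_side - n_d, cfg.rng_seed)
        c_surr = make_surrogates(control, c_side - n_c, cfg.rng_seed + 1)
        return _hstack(_hstack(disease, d_surr), _hstack(control, c_surr))
    if target < n_d:
        raise ValueError(f"target_rank {target} smaller than the {n_d} real samples")
    d_surr = make_surrogates(disease, target - n_d, cfg.rng_seed)
    return _hstack(disease, d_surr)


# ---------------------------------------------------------------------------
# Graphical lasso
# ---------------------------------------------------------------------------

def _ebic(
    precision: np.ndarray, cov_emp: np.ndarray, n: int, gamma: float
) -> float:
    p = precision.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    loglik = (n / 2.0) * (logdet - np.trace(cov_emp @ precision))
    n_edges = int(np.count_nonzero(np.triu(precision, k=1)))
    return -2.0 * loglik + n_edges * math.log(n) + 4.0 * gamma * n_edges * math.log(p)


def _standardized_covariance(design: ProfileMatrix) -> tuple[np.ndarray, int]:
    X = design.values.T  # samples x features
    n, _ = X.shape
    if n < 2:
        raise ValueError("graphical lasso needs at least 2 samples")
    variances = X.var(axis=0)
    if np.any(variances == 0):
        zero = [design.feature_names[i] for i in np.nonzero(variances == 0)[0]]
        raise ValueError(f"zero-variance features must be removed first: {zero}")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return empirical_covariance(X), n


def _lambda_grid(cov_emp: np.ndarray, cfg: LearnConfig) -> np.ndarray:
    # anchored at the smallest penalty that empties the graph entirely
    lam_max = float(np.max(np.abs(cov_emp - np.diag(np.diag(cov_emp)))))
    if lam_max <= 0:
        return np.array([])
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambdas)


def _fit_grid(cov_emp: np.ndarray, lambdas: np.ndarray) -> list[np.ndarray | None]:
    fits: list[np.ndarray | None] = []
    for lam in lambdas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = GraphicalLasso(
                    alpha=float(lam), covariance="precomputed", max_iter=200
                )
                model.fit(cov_emp)
            fits.append(model.precision_)
        except Exception:
            fits.append(None)
    return fits


def learn_gmrf(design: ProfileMatrix, cfg: LearnConfig | None = None) -> WeightedGraph:
    """Sparse GMRF by graphical lasso; edges are partial correlations.

    The penalty is selected by extended BIC (gamma ``cfg.ebic_gamma``) over
    a log-spaced grid anchored at the largest absolute off-diagonal
    covariance (above which the estimate is fully sparse). The precision
    matrix Theta is converted to partial correlations
    rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj).
    """
    cfg = cfg or LearnConfig()
    cov_emp, n = _standardized_covariance(design)
    lambdas = _lambda_grid(cov_emp, cfg)
    if lambdas.size == 0:
        # perfectly uncorrelated input: the independence model
        theta = np.diag(1.0 / np.diag(cov_emp))
        return _precision_to_graph(theta, design.feature_names)
    fits = _fit_grid(cov_emp, lambdas)
    best_score = np.inf
    best_theta: np.ndarray | None = None
    for theta in fits:
        if theta is None:
            continue
        score = _ebic(theta, cov_emp, n, cfg.ebic_gamma)
        if score < best_score:
            best_score = score
            best_theta = theta
    if best_theta is None:
        raise RuntimeError(
            f"graphical lasso failed to converge at every penalty in the grid "
            f"[{lambdas[-1]:.4g}, {lambdas[0]:.4g}]"
        )
    sign, _ = np.linalg.slogdet(best_theta)
    if sign <= 0:
        raise RuntimeError("selected precision matrix is not positive definite")
    return _precision_to_graph(best_theta, design.feature_names)


def glasso_edge_path_scores(
    design: ProfileMatrix, cfg: LearnConfig | None = None
) -> np.ndarray:
    """Edge-strength scores from the graphical-lasso regularization path.

    Each feature pair is scored by how early (at how large a penalty) its
    precision entry becomes nonzero along the grid -- the standard ranking
    for edge-support recovery, independent of any one model-selection
    criterion. Returns a symmetric p x p matrix of integer ranks
    (0 = never enters).
    """
    cfg = cfg or LearnConfig()
    cov_emp, _ = _standardized_covariance(design)
    lambdas = _lambda_grid(cov_emp, cfg)
    p = cov_emp.shape[0]
    scores = np.zeros((p, p))
    if lambdas.size == 0:
        return scores
    for rank_from_end, theta in enumerate(_fit_grid(cov_emp, lambdas)):
        if theta is None:
            continue
        entered = (theta != 0) & (scores == 0)
        np.fill_diagonal(entered, False)
        scores[entered] = cfg.n_lambdas - rank_from_end
    return scores


def _precision_to_graph(
    theta: np.ndarray, feature_names: tuple[str, ...]
) -> WeightedGraph:
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    rho = (rho + rho.T) / 2.0  # symmetrize away solver round-off
    rho[np.abs(rho) < 1e-10] = 0.0
    return WeightedGraph(feature_names, rho, SIGNED)


def prune_network(
    disease_control: WeightedGraph,
    control_only: WeightedGraph,
    magnitude_floor: float = 0.0,
    subtract_weights: bool = False,
) -> WeightedGraph:
    """Remove from the disease-control network every edge also present in
    the control-only network (normal-variation signatures).

    Default semantics is set subtraction (edges zeroed wherever the control
    counterpart exceeds ``magnitude_floor`` in magnitude); with
    ``subtract_weights`` the control weight is subtracted instead.
    """
    if set(disease_control.node_names) != set(control_only.node_names):
        warnings.warn(
            "node universes differ; pruning on the intersection", stacklevel=2
        )
    adj = disease_control.adjacency.copy()
    ctrl_idx = control_only.index
    for i, u in enumerate(disease_control.node_names):
        for j in range(i + 1, disease_control.n_nodes):
            v = disease_control.node_names[j]
            if u not in ctrl_idx or v not in ctrl_idx:
                continue
            w_ctrl = control_only.adjacency[ctrl_idx[u], ctrl_idx[v]]
            if abs(w_ctrl) > magnitude_floor:
                if subtract_weights:
                    adj[i, j] -= w_ctrl
                    adj[j, i] = adj[i, j]
                else:
                    adj[i, j] = adj[j, i] = 0.0
    return WeightedGraph(
        disease_control.node_names, adj, disease_control.weight_convention
    )


# ---------------------------------------------------------------------------
# Perturbation sets and feature selection
# ---------------------------------------------------------------------------

def select_perturbation_set(
    z_values: dict[str, float] | pd.Series,
    mode: str = "threshold",
    z_cut: float = 2.0,
    k: int | None = None,
    graph: WeightedGraph | None = None,
) -> NodeSubset | None:
    """Pick a patient's perturbation set from a z-scored profile.

    ``threshold`` mode keeps features with |z| > z_cut; ``topk`` keeps the
    k largest |z| (ties by name order). When a graph is given, names not in
    it are dropped (logged). Returns None when nothing survives.
    """
    if isinstance(z_values, pd.Series):
        z_values = {str(k_): float(v) for k_, v in z_values.items()}
    if mode == "threshold":
        chosen = [f for f, z in z_values.items() if abs(z) > z_cut]
    elif mode == "topk":
        if k is None or k < 1:
            raise ValueError("topk mode requires k >= 1")
        ordered = sorted(z_values.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
        chosen = [f for f, _ in ordered[:k]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if graph is not None:
        known = set(graph.node_names)
        dropped = [f for f in chosen if f not in known]
        if dropped:
            logger.info(
                "select_perturbation_set: %d feature(s) not in graph: %s",
                len(dropped),
                dropped,
            )
        chosen = [f for f in chosen if f in known]
    if not chosen:
        warnings.warn("empty perturbation set after selection", stacklevel=2)
        return None
    return NodeSubset(frozenset(chosen))


def select_features(results: list, min_frequency: float = 0.5) -> list[str]:
    """Features appearing in at least ``min_frequency`` of the patients'
    optimal highly connected subsets, sorted by frequency then name.

    ``results`` may be scoring results (anything with an ``optimal_subset``
    attribute) or plain iterables of feature names.
    """
    if not results:
        raise ValueError("need at least one per-patient result")
    n = len(results)
    counts: dict[str, int] = {}
    for res in results:
        subset = getattr(res, "optimal_subset", res)
        for feat in set(subset):
            counts[feat] = counts.get(feat, 0) + 1
    selected = [
        (c / n, f) for f, c in counts.items() if c / n >= min_frequency
    ]
    selected.sort(key=lambda t: (-t[0], t[1]))
    return [f for _, f in selected]
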