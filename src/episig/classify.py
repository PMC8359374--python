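"""Sample-level classification on the episignature.

Hierarchical (Ward) clustering and classical (Torgerson) multidimensional
scaling give the visual group structure; the "methylation variant
pathogenicity" (MVP) score is a calibrated probability from a linear-kernel
SVM trained on signature-probe betas with cases against everything else
(held-out controls, confounder-disorder samples and VUS are scored only);
leave-one-out cross-validation re-derives the signature without each case
in turn and checks that the held-out sample lands with the case group; the
per-sample concordance fraction counts signature probes strictly closer to
the case median than to the control median.

The MVP score carries no diagnostic claim: the 0.5 reporting label is a
convenience, and a low score does not rule out pathogenicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .config import PipelineConfig
from .io import BetaMatrix, ProbeAnnotation, SampleSheet
from .model import EpisignatureModel, MVPClassifier


class ClassifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Clustering and ordination


def ward_cluster(beta_signature: pd.DataFrame
                 ) -> tuple[np.ndarray, pd.Series]:
    """Ward-linkage hierarchical clustering of samples on signature betas.

    ``beta_signature`` is probes x samples. Returns the scipy linkage matrix
    and a 2-cluster flat assignment (labels 1/2) indexed by sample id.
    Merge heights are non-decreasing (Ward's criterion is monotone).
    """
    x = beta_signature.to_numpy(dtype=float).T
    if x.shape[0] < 2:
        raise ClassifyError("need at least 2 samples to cluster")
    z = hierarchy.linkage(x, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(z, t=2, criterion="maxclust")
    return z, pd.Series(labels, index=list(beta_signature.columns))


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (branch lengths
    from merge heights)."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def classical_mds(x: np.ndarray | pd.DataFrame, n_dims: int = 2,
                  dissimilarity: bool = False) -> np.ndarray:
    """Classical (Torgerson) MDS by scaling of pairwise Euclidean distances.

    ``x`` is samples x features (or a square distance matrix when
    ``dissimilarity=True``). The squared-distance matrix is double-centred
    and eigendecomposed; coordinates on the top ``n_dims`` components are
    returned. When the configuration embeds exactly in ``n_dims``
    dimensions the embedded pairwise distances reproduce the originals; the
    configuration is recovered only up to rotation/reflection. Negative
    eigenvalues (non-Euclidean input) are truncated with a warning when they
    dominate.
    """
    a = np.asarray(x, dtype=float)
    if dissimilarity:
        d = a
    else:
        if a.shape[0] < 3:
            raise ClassifyError("need at least 3 samples for MDS")
        diff = a[:, None, :] - a[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or (evals < 0).sum() and abs(evals[-1]) > evals[0]:
        import warnings
        warnings.warn("distance matrix is strongly non-Euclidean; "
                      "negative eigenvalues truncated")
    k = min(n_dims, n)
    lam = np.clip(evals[:k], 0.0, None)
    return evecs[:, :k] * np.sqrt(lam)


# ---------------------------------------------------------------------------
# MVP classifier


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # 1-D logistic fit on decision values; light regularisation keeps the
    # map finite on separable data while leaving scores near 0/1.
    lr = LogisticRegression(C=1e4, solver="lbfgs", max_iter=1000)
    lr.fit(decision.reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def train_mvp(beta: BetaMatrix, sheet: SampleSheet,
              signature_probes: list[str], train_fraction: float = 0.75,
              seed: int = 0) -> tuple[MVPClassifier, pd.DataFrame]:
    """Train the MVP classifier on signature-probe betas.

    Training set: every ``case`` sample, plus ``train_fraction`` of the
    controls and of each confounder-disorder pool (stratified by pool,
    seeded shuffle of sorted ids). The binary target is case vs rest. The
    remaining controls/confounders and all ``vus`` samples are held out and
    scored only. Returns the classifier and a per-sample role table
    (``train`` / ``test``).
    """
    if not signature_probes:
        raise ClassifyError("signature probe set is empty")
    rng = np.random.default_rng(seed)
    cases = sheet.ids_of("case")
    if not cases:
        raise ClassifyError("no case samples to train on")

    def split(ids: list[str]) -> tuple[list[str], list[str]]:
        ids = sorted(ids)
        if len(ids) < 2:
            raise ClassifyError(
                f"pool of size {len(ids)} too small to split (need >= 2)")
        order = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train = [ids[i] for i in sorted(order[:n_train])]
        test = [ids[i] for i in sorted(order[n_train:])]
        return train, test

    train_ids = list(cases)
    test_ids: list[str] = []
    tr, te = split(sheet.ids_of("control"))
    train_ids += tr
    test_ids += te
    dis_t = sheet.table[sheet.table["group"] == "other_disorder"]
    if len(dis_t):
        if "disorder" in dis_t.columns:
            keys = dis_t["disorder"].fillna("").replace("", "pool")
        else:
            keys = pd.Series("pool", index=dis_t.index)
        for _, grp in dis_t.groupby(keys):
            tr, te = split(list(grp["sample_id"]))
            train_ids += tr
            test_ids += te
    test_ids += sheet.ids_of("vus")

    x_train = beta.values.loc[signature_probes, train_ids].to_numpy().T
    y_train = np.array([1 if s in set(cases) else 0 for s in train_ids])
    svc = SVC(kernel="linear", C=1.0)
    svc.fit(x_train, y_train)
    w = svc.coef_[0]
    b = float(svc.intercept_[0])
    decision = x_train @ w + b
    a, c = _platt_fit(decision, y_train)
    clf = MVPClassifier(probe_ids=list(signature_probes), weights=w, bias=b,
                        platt_a=a, platt_b=c)
    roles = pd.DataFrame(
        {"sample_id": train_ids + test_ids,
         "training_role": ["train"] * len(train_ids) + ["test"] * len(test_ids)})
    return clf, roles


def mvp_score(classifier: MVPClassifier, beta: BetaMatrix) -> pd.Series:
    """Calibrated case-class probability per sample, in [0, 1]."""
    missing = [p for p in classifier.probe_ids if p not in set(beta.probe_ids)]
    if missing:
        raise ClassifyError(
            f"{len(missing)} signature probe(s) missing from matrix, "
            f"first: {missing[:3]}")
    x = beta.values.loc[classifier.probe_ids].to_numpy(dtype=float).T
    return pd.Series(classifier.score(x), index=beta.sample_ids,
                     name="mvp_score")


def score_samples(classifier: MVPClassifier, beta: BetaMatrix,
                  roles: pd.DataFrame | None = None) -> pd.DataFrame:
    """MVP result table: score, reporting label, training role."""
    scores = mvp_score(classifier, beta)
    out = pd.DataFrame({
        "sample_id": scores.index,
        "mvp_score": scores.to_numpy(),
        "predicted_class": np.where(scores.to_numpy() >= 0.5,
                                    "case-like", "control-like"),
    })
    if roles is not None:
        out = out.merge(roles, on="sample_id", how="left")
        out["training_role"] = out["training_role"].fillna("test")
    return out


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation


def loo_cross_validate(beta: BetaMatrix, sheet: SampleSheet,
                       ann: ProbeAnnotation, config: PipelineConfig,
                       cell_reference: pd.DataFrame | None = None
                       ) -> pd.DataFrame:
    """Hold out each case in turn, re-derive the signature from the rest,
    and assign the held-out sample to the nearer group centroid in MDS
    space.

    Returns one row per round: held-out id, re-derived signature size,
    whether the round succeeded, and whether the held-out case was assigned
    to the case centroid. Rounds whose signature derivation fails are
    reported and skipped.
    """
    from .discovery import derive_episignature

    cases = sheet.ids_of("case")
    if len(cases) < 3:
        raise ClassifyError("leave-one-out needs at least 3 cases")
    rows = []
    for held in cases:
        rest = [c for c in cases if c != held]
        try:
            res = derive_episignature(beta, sheet, ann, config,
                                      cell_reference=cell_reference,
                                      case_ids=rest)
            probes = res.model.probe_ids
            if not probes:
                raise ClassifyError("empty signature")
            samples = res.matched.case_ids + res.matched.control_ids + [held]
            sub = beta.values.loc[probes, samples]
            coords = classical_mds(sub.to_numpy(dtype=float).T, n_dims=2)
            n_case = len(res.matched.case_ids)
            n_ctrl = len(res.matched.control_ids)
            case_centroid = coords[:n_case].mean(axis=0)
            ctrl_centroid = coords[n_case:n_case + n_ctrl].mean(axis=0)
            held_pt = coords[-1]
            to_case = float(np.linalg.norm(held_pt - case_centroid))
            to_ctrl = float(np.linalg.norm(held_pt - ctrl_centroid))
            rows.append(dict(held_out=held, signature_size=len(probes),
                             ok=True, assigned="case" if to_case < to_ctrl
                             else "control",
                             correct=to_case < to_ctrl))
        except (ClassifyError, ValueError) as exc:
            rows.append(dict(held_out=held, signature_size=0, ok=False,
                             assigned=f"skipped: {exc}", correct=False))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Concordance


def concordance_fraction(sample_beta: np.ndarray, case_median: np.ndarray,
                         control_median: np.ndarray) -> float:
    """Share of probes strictly closer to the case median than the control
    median: per probe ``a = |b - control| - |b - case|``; ties (a == 0)
    count as not case-like. Invariant to probe order and to any common
    affine rescaling of sample and medians."""
    b = np.asarray(sample_beta, dtype=float)
    if b.size == 0:
        raise ClassifyError("empty probe set")
    a = np.abs(b - np.asarray(control_median, dtype=float)) \
        - np.abs(b - np.asarray(case_median, dtype=float))
    return float((a > 0).mean())


def concordance_table(beta: BetaMatrix, model: EpisignatureModel,
                      probes: list[str] | None = None) -> pd.DataFrame:
    """Per-sample concordance fractions over the model's probes (or a
    supplied subset, e.g. the probes inside called DMRs)."""
    ids = probes if probes is not None else model.probe_ids
    idx = [model.probe_ids.index(p) for p in ids]
    case_med = model.case_median[idx]
    ctrl_med = model.control_median[idx]
    sub = beta.values.loc[ids]
    rows = [dict(sample_id=s,
                 fraction_case_like=concordance_fraction(
                     sub[s].to_numpy(dtype=float), case_med, ctrl_med))
            for s in sub.columns]
    return pd.DataFrame(rows)
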