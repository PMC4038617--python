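"""Probabilistic classification and Bayesian expert-system refinement.

A calibrated multiclass classifier turns the band stack into one probability
("rule") image per land-cover class; those per-cell probabilities act as
priors P(B_j). Ancillary categorical evidence layers (terrain position,
elevation class) then update the priors cell by cell through Bayes' rule,

    P(B_j | A) = P(A | B_j) P(B_j) / sum_i P(A | B_i) P(B_i),

applied sequentially over the evidence items (the posterior after one item
becomes the prior for the next, which under conditional independence of the
evidence equals a single update with the product of likelihood vectors).
Each cell is finally relabelled by its maximum-posterior class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grids import DEFAULT_SCHEME, ClassScheme, Grid, NODATA_CODE, PlotSample
from .terrain import EvidenceLayer

__all__ = [
    "RuleStack",
    "ProbabilityRuleTable",
    "BaseClassifier",
    "fit_base_classifier",
    "predict_rule_stack",
    "bayes_update",
    "evaluate_evidence",
    "relabel_max_posterior",
    "estimate_rule_table",
]


@dataclass
class RuleStack:
    """Per-class probability grids sharing one geometry.

    ``probs`` has shape (n_classes, nrows, ncols); cells are normalised to
    sum to 1, and nodata cells carry NaN in every layer. A PosteriorStack is
    the same container holding P(B_j | A) after evidence evaluation.
    """

    probs: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    scheme: ClassScheme = DEFAULT_SCHEME
    n_flagged: int = 0  # cells whose evidence was impossible under every class

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[0] != self.scheme.n_classes:
            raise ValueError(f"probs must be (n_classes, nrows, ncols), got {p.shape}")
        valid = ~np.isnan(p).any(axis=0)
        if valid.any():
            sub = p[:, valid]
            if sub.min() < -1e-12:
                raise ValueError("negative probabilities in rule stack")
            sums = sub.sum(axis=0)
            if np.any(sums <= 0):
                raise ValueError("cell with all-zero probabilities; cannot normalise")
            p[:, valid] = sub / sums
        self.probs = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[1:]

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.probs).any(axis=0)

    def grid(self, j: int) -> Grid:
        return Grid(self.probs[j], self.cell_size, self.origin, nodata=np.nan)


class ProbabilityRuleTable:
    """Conditional probabilities P(A = a | B_j) for categorical evidence.

    One row per (evidence layer, evidence value, class). For each layer and
    class, the probabilities over that layer's values must sum to 1 — each
    (layer, class) column is a categorical likelihood over the evidence
    values. Serialised as CSV with header ``layer,value,class,probability``.
    """

    def __init__(self, entries: pd.DataFrame, scheme: ClassScheme = DEFAULT_SCHEME):
        required = {"layer", "value", "class", "probability"}
        if not required.issubset(entries.columns):
            raise ValueError(f"rule table needs columns {sorted(required)}")
        df = entries.copy()
        df["value"] = df["value"].astype(int)
        df["probability"] = df["probability"].astype(float)
        if (df["probability"] < 0).any() or (df["probability"] > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        unknown = set(df["class"]) - set(scheme.names)
        if unknown:
            raise ValueError(f"rule table references unknown classes {sorted(unknown)}")
        for (layer, cls), g in df.groupby(["layer", "class"]):
            if abs(g["probability"].sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"P(A|B) over values of layer {layer!r} for class {cls!r} "
                    f"sums to {g['probability'].sum():.12f}, expected 1"
                )
        self.entries = df
        self.scheme = scheme
        # (layer, value) -> likelihood vector over scheme order
        self._lut: dict[tuple[str, int], np.ndarray] = {}
        for (layer, value), g in df.groupby(["layer", "value"]):
            vec = np.zeros(scheme.n_classes)
            for _, row in g.iterrows():
                vec[scheme.code(row["class"])] = row["probability"]
            self._lut[(str(layer), int(value))] = vec

    def likelihood(self, layer: str, value: int) -> np.ndarray:
        try:
            return self._lut[(layer, int(value))]
        except KeyError:
            raise KeyError(f"evidence value {value} of layer {layer!r} not covered by the rule table") from None

    def layers(self) -> list[str]:
        return list(dict.fromkeys(self.entries["layer"]))

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scheme: ClassScheme = DEFAULT_SCHEME) -> "ProbabilityRuleTable":
        return cls(pd.read_csv(path, comment="#"), scheme)


@dataclass
class BaseClassifier:
    """A fitted probabilistic classifier over the full class scheme.

    Classes absent from training receive probability zero; predictions are
    reported in scheme order regardless of which classes were seen.
    """

    pipeline: Pipeline
    scheme: ClassScheme
    classes_seen: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raw = self.pipeline.predict_proba(X)
        out = np.zeros((X.shape[0], self.scheme.n_classes))
        out[:, self.classes_seen] = raw
        return out


def fit_base_classifier(
    plots: PlotSample,
    bands: list[Grid],
    scheme: ClassScheme = DEFAULT_SCHEME,
    seed: int = 0,
    method: str = "mlc",
) -> BaseClassifier:
    """Fit the probabilistic base classifier on the training half of the plots.

    Features are the band values at each plot's centre cell. The default
    ``method="mlc"`` is Gaussian maximum-likelihood classification with
    per-class diagonal covariances (Gaussian naive Bayes) — the classic
    remote-sensing supervised classifier family, whose per-class
    probabilities are well calibrated for near-Gaussian spectra and which
    stays stable for classes with very few training plots.
    ``method="svm"`` fits an RBF support-vector machine with cross-validated
    sigmoid probability calibration instead. The module contract is only
    "per-class probability per cell"; any calibrated multiclass classifier
    satisfies it.
    """
    train = plots.half("train") if "test" in set(plots.split) else plots
    labels = train.true_class.astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain fewer than two classes")
    idx = [bands[0].cell_index(x, y) for x, y in zip(train.x, train.y)]
    rows = np.array([r for r, _ in idx])
    cols = np.array([c for _, c in idx])
    X = np.column_stack([np.asarray(b.values, dtype=float)[rows, cols] for b in bands])
    counts = np.bincount(labels)
    min_count = int(counts[counts > 0].min())
    if min_count < 2:
        raise ValueError("every training class needs at least two plots per class")
    if method == "mlc":
        pipe = Pipeline([("mlc", GaussianNB())])
        final = "mlc"
    elif method == "svm":
        svm = SVC(kernel="rbf", C=10.0, gamma="scale", random_state=int(seed))
        cv = int(min(5, min_count))  # rare classes cap the calibration folds
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", CalibratedClassifierCV(svm, method="sigmoid", cv=cv, ensemble=False)),
            ]
        )
        final = "svm"
    else:
        raise ValueError(f"unknown classifier method {method!r}")
    pipe.fit(X, labels)
    return BaseClassifier(pipe, scheme, np.asarray(pipe.named_steps[final].classes_, dtype=int))


def predict_rule_stack(model: BaseClassifier, bands: list[Grid]) -> RuleStack:
    """Predict the per-class probability ("rule") image stack for a band stack.

    Cells where any band is nodata/NaN propagate to NaN across all layers.
    Probabilities are renormalised cellwise (classifier outputs are not
    guaranteed to sum exactly to 1).
    """
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise ValueError("bands must share shape")
    stack = np.stack([np.asarray(b.values, dtype=float) for b in bands])
    for b in bands:
        if b.nodata is not None and not np.isnan(b.nodata):
            stack[np.isclose(stack, b.nodata)] = np.nan
    X = stack.reshape(len(bands), -1).T
    valid = ~np.isnan(X).any(axis=1)
    probs = np.full((X.shape[0], model.scheme.n_classes), np.nan)
    if valid.any():
        probs[valid] = model.predict_proba(X[valid])
    cube = probs.T.reshape(model.scheme.n_classes, *bands[0].shape)
    return RuleStack(cube, bands[0].cell_size, bands[0].origin, model.scheme)


def bayes_update(prior: np.ndarray, likelihood: np.ndarray) -> np.ndarray:
    """One Bayes step: posterior_j ∝ likelihood_j · prior_j, normalised.

    ``prior`` must sum to 1 and ``likelihood`` lie in [0, 1]. If the
    normalising constant is zero (the evidence is impossible under every
    class) the prior is returned unchanged — callers treating grids flag and
    count such cells.
    """
    prior = np.asarray(prior, dtype=float)
    like = np.asarray(likelihood, dtype=float)
    if prior.shape != like.shape:
        raise ValueError("prior and likelihood must share shape")
    if abs(prior.sum() - 1.0) > 1e-6:
        raise ValueError(f"prior must sum to 1, sums to {prior.sum()}")
    if like.min() < 0 or like.max() > 1:
        raise ValueError("likelihood entries must lie in [0, 1]")
    num = like * prior
    denom = num.sum()
    if denom <= 0:
        return prior.copy()
    return num / denom


def evaluate_evidence(
    rules: RuleStack,
    evidence: list[EvidenceLayer],
    table: ProbabilityRuleTable,
) -> RuleStack:
    """Forward-chain every evidence layer through Bayes' rule, cell by cell.

    Layers are applied in the given order; the posterior after layer k is the
    prior for layer k+1. With zero layers the result equals the input stack.
    Cells whose evidence value is nodata are left un-updated by that layer;
    an evidence value missing from the table is an error naming the layer and
    value. Cells where the evidence is impossible under every class keep
    their prior and are counted in ``n_flagged``.
    """
    post = rules.probs.copy()
    n_classes = rules.scheme.n_classes
    flagged = np.zeros(rules.shape, dtype=bool)
    for layer in evidence:
        if layer.grid.shape != rules.shape:
            raise ValueError(f"evidence layer {layer.name!r} shape {layer.grid.shape} != stack shape {rules.shape}")
        values = layer.grid.values
        lmask = layer.grid.valid_mask()
        present = np.unique(values[lmask])
        covered = {v for (lname, v) in table._lut if lname == layer.name}
        for v in present:
            if int(v) not in covered:
                raise KeyError(f"evidence value {int(v)} of layer {layer.name!r} not covered by the rule table")
        like = np.ones((n_classes,) + rules.shape)
        for v in present:
            vec = table.likelihood(layer.name, int(v))
            like[:, values == v] = vec[:, None]
        like[:, ~lmask] = 1.0  # nodata evidence: uninformative
        num = like * post
        denom = num.sum(axis=0)
        zero = (denom <= 0) & rules.valid_mask()
        flagged |= zero
        safe = denom.copy()
        safe[safe <= 0] = 1.0
        updated = num / safe
        updated[:, zero] = post[:, zero]
        post = updated
    return RuleStack(
        post, rules.cell_size, rules.origin, rules.scheme, n_flagged=int(flagged.sum())
    )


def relabel_max_posterior(post: RuleStack) -> Grid:
    """Relabel every cell by its maximum-posterior class.

    Ties break to the lowest class index in scheme order; all-nodata cells
    map to the categorical nodata code.
    """
    valid = post.valid_mask()
    filled = np.where(np.isnan(post.probs), -np.inf, post.probs)
    codes = np.argmax(filled, axis=0).astype(np.uint8)  # argmax takes the first maximum
    codes[~valid] = NODATA_CODE
    return Grid(codes, post.cell_size, post.origin, nodata=NODATA_CODE)


def estimate_rule_table(
    evidence: list[EvidenceLayer],
    truth: Grid,
    plots: PlotSample | None = None,
    scheme: ClassScheme = DEFAULT_SCHEME,
    alpha: float = 1.0,
) -> ProbabilityRuleTable:
    """Estimate P(A = a | B_j) empirically, with Laplace smoothing ``alpha``.

    When ``plots`` is given, frequencies come from the training half only
    (evidence value vs. plot label) — the field-realistic route. Otherwise
    the full truth map is tabulated. Classes never observed fall back to the
    uniform likelihood over each layer's declared values.
    """
    rows = []
    if plots is not None:
        train = plots.half("train")
        cells = [truth.cell_index(x, y) for x, y in zip(train.x, train.y)]
        labels = train.true_class.astype(int)
    else:
        mask = truth.valid_mask()
        cells = list(zip(*np.nonzero(mask)))
        labels = truth.values[mask].astype(int)
    for layer in evidence:
        values = sorted(layer.categories)
        ev = np.array([layer.grid.values[r, c] for (r, c) in cells])
        for j, cls in enumerate(scheme.names):
            sel = ev[labels == j]
            sel = sel[sel != NODATA_CODE] if layer.grid.nodata is not None else sel
            counts = np.array([(sel == v).sum() for v in values], dtype=float)
            probs = (counts + alpha) / (counts.sum() + alpha * len(values))
            probs /= probs.sum()
            for v, p in zip(values, probs):
                rows.append({"layer": layer.name, "value": int(v), "class": cls, "probability": p})
    return ProbabilityRuleTable(pd.DataFrame(rows), scheme)
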