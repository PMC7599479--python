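"""Orthogonal projections to latent structures discriminant analysis
(OPLS-DA) for a single binary response.

The NIPALS-style single-y algorithm first extracts ``n_ortho`` components of
X-variation orthogonal to the class code, deflates them from X, and then
fits one predictive PLS component on the deflated matrix. Class codes are
fixed at control=0 / cancer=1 with an a priori decision cutoff of 0.5.

Model quality is summarized by R2Y (fraction of class-code variance
explained on training data) and Q2 (its cross-validated analogue from
stratified k-fold held-out predictions, which may be negative).
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500

CONTROL_CODE = 0.0
CASE_CODE = 1.0
CUTOFF = 0.5


@dataclass(frozen=True)
class ClassCoding:
    """Label -> code mapping with the fixed 0.5 decision cutoff."""

    control_label: str = "control"
    case_label: str = "case"
    cutoff: float = CUTOFF

    def __post_init__(self) -> None:
        if not CONTROL_CODE < self.cutoff < CASE_CODE:
            raise ValueError("cutoff must lie strictly between the class codes")

    def encode(self, labels) -> np.ndarray:
        out = np.empty(len(labels))
        for i, lab in enumerate(labels):
            if lab == self.control_label:
                out[i] = CONTROL_CODE
            elif lab == self.case_label:
                out[i] = CASE_CODE
            else:
                raise ValueError(f"unknown label {lab!r}")
        return out

    def decode(self, y_hat: np.ndarray) -> list[str]:
        return [self.case_label if v >= self.cutoff else self.control_label for v in y_hat]


@dataclass
class OplsModel:
    """Fitted O-PLS model with one predictive component."""

    mean_x: np.ndarray
    scale_x: np.ndarray
    w: np.ndarray            # predictive weights, unit norm
    p: np.ndarray            # predictive loadings
    t: np.ndarray            # predictive scores (training)
    c: float                 # y-loading
    W_ortho: np.ndarray      # (n_ortho, n_bins)
    P_ortho: np.ndarray      # (n_ortho, n_bins)
    T_ortho: np.ndarray      # (n_train, n_ortho)
    n_ortho: int
    y_mean: float
    r2y: float
    q2: float | None = None
    bin_edges: np.ndarray | None = field(default=None, repr=False)


def _scale_vectors(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scaling == "center":
        scale = np.ones(X.shape[1])
    elif scaling == "uv":
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
    elif scaling == "pareto":
        scale = np.sqrt(X.std(axis=0, ddof=1))
        scale[scale == 0] = 1.0
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return mean, scale


def _pls_weight(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """NIPALS weight for a single response: converges to w ∝ X'y."""
    w = X.T @ y
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate class vector: X'y vanished")
    w /= norm
    for _ in range(NIPALS_MAX_ITER):
        t = X @ w
        c = (t @ y) / (t @ t)
        w_new = X.T @ y * c
        w_new /= np.linalg.norm(w_new)
        if np.linalg.norm(w_new - w) < NIPALS_TOL:
            return w_new
        w = w_new
    raise RuntimeError("NIPALS did not converge")


def fit_opls(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 2,
    scaling: str = "center",
    bin_edges: np.ndarray | None = None,
) -> OplsModel:
    """Fit a single-response O-PLS model with ``n_ortho`` orthogonal
    components and one predictive component.

    Each orthogonal component is the part of the current X-loading that is
    orthogonal to the predictive weight direction; its variation is deflated
    from X before the final predictive component is fitted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y sample counts differ")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("y must contain two classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_ortho >= rank:
        raise ValueError(f"n_ortho={n_ortho} >= rank of centered X ({rank})")

    mean_x, scale_x = _scale_vectors(X, scaling)
    Xc = (X - mean_x) / scale_x
    y_mean = float(y.mean())
    yc = y - y_mean

    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        w = _pls_weight(Xc, yc)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n = np.linalg.norm(w_o)
        if n < 1e-12:
            break  # no class-orthogonal variation left
        w_o /= n
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    w = _pls_weight(Xc, yc)
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    c = float((t @ yc) / (t @ t))

    y_hat = t * c + y_mean
    ss_tot = float(((y - y_mean) ** 2).sum())
    r2y = 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot

    n_bins = X.shape[1]
    return OplsModel(
        mean_x=mean_x,
        scale_x=scale_x,
        w=w,
        p=p,
        t=t,
        c=c,
        W_ortho=np.array(W_o).reshape(len(W_o), n_bins),
        P_ortho=np.array(P_o).reshape(len(P_o), n_bins),
        T_ortho=np.array(T_o).T.reshape(X.shape[0], len(T_o)),
        n_ortho=len(W_o),
        y_mean=y_mean,
        r2y=r2y,
        bin_edges=None if bin_edges is None else np.asarray(bin_edges, float),
    )


def predict(model: OplsModel, X_new: np.ndarray,
            bin_edges: np.ndarray | None = None) -> np.ndarray:
    """Continuous class predictions for new samples.

    Applies the training centring/scaling, strips the fitted orthogonal
    components from each sample, projects onto the predictive weights and
    returns ``y_hat = t * c + y_mean``. A bin-layout mismatch (column count
    or edges) is a hard error, never a silent reindex.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.w.size:
        raise ValueError(
            f"bin-layout mismatch: model has {model.w.size} bins, data {X_new.shape[1]}"
        )
    if bin_edges is not None and model.bin_edges is not None:
        if bin_edges.shape != model.bin_edges.shape or not np.allclose(
            bin_edges, model.bin_edges
        ):
            raise ValueError("bin-layout mismatch: edges differ from training")
    Xc = (X_new - model.mean_x) / model.scale_x
    for k in range(model.n_ortho):
        t_o = Xc @ model.W_ortho[k]
        Xc = Xc - np.outer(t_o, model.P_ortho[k])
    t = Xc @ model.w
    return t * model.c + model.y_mean


def predict_scores(model: OplsModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive and orthogonal scores for new samples (score-plot export)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Xc = (X_new - model.mean_x) / model.scale_x
    T_o = np.zeros((X_new.shape[0], model.n_ortho))
    for k in range(model.n_ortho):
        T_o[:, k] = Xc @ model.W_ortho[k]
        Xc = Xc - np.outer(T_o[:, k], model.P_ortho[k])
    return Xc @ model.w, T_o


def classify(y_hat: np.ndarray, coding: ClassCoding | None = None) -> list[str]:
    """Threshold continuous predictions at the a priori cutoff 0.5.

    A prediction exactly at the cutoff is called cancer (documented tie
    rule).
    """
    if coding is None:
        coding = ClassCoding()
    return coding.decode(np.atleast_1d(np.asarray(y_hat, dtype=float)))


def q2_cross_val(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 2,
    folds: int = 7,
    seed: int = 0,
    scaling: str = "center",
) -> float:
    """Cross-validated Q2 from stratified k-fold held-out predictions.

    Q2 = 1 - PRESS / total y sum of squares, with PRESS accumulated over
    each fold's held-out predictions from a model fitted on the remaining
    samples. Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("each fold must keep both classes in training")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    for train_idx, test_idx in skf.split(X, y):
        m = fit_opls(X[train_idx], y[train_idx], n_ortho=n_ortho, scaling=scaling)
        y_hat = predict(m, X[test_idx])
        press += float(((y[test_idx] - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


# ---------------------------------------------------------------------------
# serialization

def _enc(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=np.float64)
    return {"shape": list(a.shape), "data": base64.b64encode(a.tobytes()).decode()}


def _dec(d: dict) -> np.ndarray:
    return np.frombuffer(base64.b64decode(d["data"]), dtype=np.float64).reshape(d["shape"])


def save_model(model: OplsModel, path: str | Path) -> None:
    payload = {
        "format_version": 1,
        "n_ortho": model.n_ortho,
        "c": model.c,
        "y_mean": model.y_mean,
        "r2y": model.r2y,
        "q2": model.q2,
        "arrays": {
            name: _enc(getattr(model, name))
            for name in ("mean_x", "scale_x", "w", "p", "t", "W_ortho", "P_ortho", "T_ortho")
        },
    }
    if model.bin_edges is not None:
        payload["arrays"]["bin_edges"] = _enc(model.bin_edges)
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> OplsModel:
    d = json.loads(Path(path).read_text())
    arrays = {k: _dec(v) for k, v in d["arrays"].items()}
    return OplsModel(
        mean_x=arrays["mean_x"], scale_x=arrays["scale_x"], w=arrays["w"],
        p=arrays["p"], t=arrays["t"], c=d["c"], W_ortho=arrays["W_ortho"],
        P_ortho=arrays["P_ortho"], T_ortho=arrays["T_ortho"],
        n_ortho=d["n_ortho"], y_mean=d["y_mean"], r2y=d["r2y"], q2=d["q2"],
        bin_edges=arrays.get("bin_edges"),
    )
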