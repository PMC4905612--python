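"""Multi-view boosting of TF-target prediction, and the CCA interplay view.

Transcription-factor targets can be recognised two independent ways: the
promoter carries a binding-site motif (a *sequence* readout, scored with a
PWM), and the gene sits on the regulon's positional lattice (a *position*
readout, the positional score of the periodicity analysis).  This module
combines both with a multi-view variant of AdaBoost: at every iteration
each view proposes its best decision stump over its own feature columns,
the lower-error view wins the round, and its stump joins the ensemble with
the usual weight alpha = 0.5 * ln((1 - eps) / eps).  The final classifier
is the sign of F(x) = sum_t alpha_t * h_t(x).

The interplay analysis extracts, per gene, the weighted stump outputs of
the position-selected iterations (block X) and of the sequence-selected
iterations (block Y), and runs a ridge-regularised canonical correlation
analysis on the two blocks.  Opposite-sign loadings of the two blocks on
the first variate indicate an anti-correlated division of labour: genes
carried by a strong binding site tend not to be the genes carried by a
good lattice position, and vice versa.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import ALPHABET, FeatureSet, MotifMatrix
from .phase_clustering import positional_scores

__all__ = [
    "LabeledGene",
    "WeakClassifier",
    "BoostModel",
    "CCAResult",
    "pwm_score",
    "build_view_features",
    "train_multiview_boost",
    "predict_scores",
    "extract_iteration_scores",
    "canonical_correlations",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1
_EPS_FLOOR = 1e-12  # alpha stays finite when a stump separates perfectly

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class LabeledGene:
    """A gene with its regulatory sequence and target/non-target label."""

    name: str
    position: int
    regulatory_sequence: str
    label: int  # +1 target, -1 non-target

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        seq = self.regulatory_sequence.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"gene {self.name!r}: sequence has non-ACGTN characters")
        object.__setattr__(self, "regulatory_sequence", seq)


@dataclass(frozen=True)
class WeakClassifier:
    """One decision stump: view, feature column, threshold, polarity, weight."""

    view: str  # "sequence" or "position"
    column: str  # motif-variant id or period, as a column name
    threshold: float
    polarity: int  # +1: predict +1 above threshold; -1: the reverse
    alpha: float
    iteration: int
    error: float

    def predict(self, values: np.ndarray) -> np.ndarray:
        return np.where(values > self.threshold, self.polarity, -self.polarity)


@dataclass
class BoostModel:
    """The strong classifier: ordered stumps plus the training trace."""

    classifiers: list[WeakClassifier]
    weight_history: list[np.ndarray] = field(default_factory=list)
    view_trace: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.classifiers)


def pwm_score(sequence: str, motif: MotifMatrix) -> float:
    """Best log-odds PWM match over all windows on both strands.

    Windows containing N are skipped.  Returns -inf when no window is
    scoreable (all-N sequences).
    """
    seq = sequence.upper()
    w = motif.width
    if len(seq) < w:
        raise ValueError(f"sequence length {len(seq)} < motif width {w}")
    lo = motif.log_odds
    best = -np.inf
    for s in (seq, seq.translate(_COMPLEMENT)[::-1]):
        enc = np.frombuffer(s.encode(), dtype=np.uint8)
        code = np.full(enc.size, 4, dtype=np.int64)
        for i, base in enumerate(ALPHABET):
            code[enc == ord(base)] = i
        n_win = len(s) - w + 1
        scores = np.zeros(n_win)
        valid = np.ones(n_win, dtype=bool)
        for j in range(w):
            cj = code[j : j + n_win]
            ok = cj < 4
            valid &= ok
            scores += np.where(ok, lo[j, np.minimum(cj, 3)], 0.0)
        if valid.any():
            best = max(best, float(scores[valid].max()))
    return best


def build_view_features(
    genes: Sequence[LabeledGene],
    motif_variants: Mapping[str, MotifMatrix],
    significant_periods: Sequence[float],
    fs: FeatureSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the two view tables: sequence scores and positional scores.

    Sequence view: gene x motif-variant best PWM score.  Position view:
    gene x period positional score, computed jointly over all usable genes
    (a positional score is relative to the whole set).  Genes whose
    sequence cannot be scored under any variant (e.g. all-N) are excluded
    with a warning naming them.
    """
    if not motif_variants or not len(significant_periods):
        raise ValueError("need at least one motif variant and one period")
    seq_scores: dict[str, dict[str, float]] = {}
    usable: list[LabeledGene] = []
    dropped: list[str] = []
    for g in genes:
        row = {vid: pwm_score(g.regulatory_sequence, m) for vid, m in motif_variants.items()}
        if all(not np.isfinite(v) for v in row.values()):
            dropped.append(g.name)
            continue
        seq_scores[g.name] = row
        usable.append(g)
    if dropped:
        warnings.warn(f"excluded genes with unscoreable sequences: {', '.join(dropped)}")
    if not usable:
        raise ValueError("no gene with a scoreable sequence")
    names = [g.name for g in usable]
    sequence = pd.DataFrame.from_dict(seq_scores, orient="index").loc[names]
    sequence.replace(-np.inf, sequence[np.isfinite(sequence)].min().min(), inplace=True)
    positions = np.array([g.position for g in usable], dtype=float)
    position = pd.DataFrame(
        {f"P{p:g}": positional_scores(positions, float(p)) for p in significant_periods},
        index=names,
    )
    return sequence, position


def _best_stump_for_column(
    values: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float, int]:
    """(error, threshold, polarity) minimising weighted error for one column.

    Threshold grid: midpoints of sorted unique values.  For polarity +1 the
    stump predicts +1 strictly above the threshold.
    """
    uniq = np.unique(values)
    if uniq.size < 2:
        return (float(np.sum(w[y == +1])), float(uniq[0]), +1)  # all predicted -1
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    # a midpoint of two adjacent floats can round up onto the upper value,
    # silently moving it to the wrong side of the strict '>' split; fall
    # back to the lower value (same partition) in that case
    thresholds = np.where(thresholds < uniq[1:], thresholds, uniq[:-1])
    order = np.argsort(values, kind="mergesort")
    v, yy, ww = values[order], y[order], w[order]
    wp = np.cumsum(ww * (yy == +1))
    wn = np.cumsum(ww * (yy == -1))
    total_p, total_n = wp[-1], wn[-1]
    # index of last value <= t for each midpoint threshold
    idx = np.searchsorted(v, thresholds, side="right") - 1
    err_plus = wp[idx] + (total_n - wn[idx])  # predict +1 above t
    err_minus = (total_p + total_n) - err_plus
    i_plus = int(np.argmin(err_plus))
    i_minus = int(np.argmin(err_minus))
    if err_plus[i_plus] <= err_minus[i_minus]:
        return float(err_plus[i_plus]), float(thresholds[i_plus]), +1
    return float(err_minus[i_minus]), float(thresholds[i_minus]), -1


def _best_stump_for_view(
    table: pd.DataFrame, y: np.ndarray, w: np.ndarray
) -> tuple[float, str, float, int]:
    best: tuple[float, str, float, int] | None = None
    for col in table.columns:
        err, thr, pol = _best_stump_for_column(table[col].to_numpy(float), y, w)
        if best is None or err < best[0]:
            best = (err, str(col), thr, pol)
    assert best is not None
    return best


def train_multiview_boost(
    features: Mapping[str, pd.DataFrame],
    labels: Sequence[int] | np.ndarray,
    T: int = 10,
    seed: int | None = None,
) -> BoostModel:
    """Train the multi-view AdaBoost ensemble.

    ``features`` maps view name ("sequence", "position") to a gene x column
    table; all tables must share the same row order as ``labels``.  Class
    imbalance is absorbed in the initial weights (each class starts with
    total weight 1/2).  Each iteration keeps the lower-error view's stump;
    training stops early when no stump beats chance (eps >= 1/2) or when a
    stump is perfect (eps = 0).  ``seed`` is accepted for interface
    symmetry; training itself is deterministic.
    """
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {-1, +1}:
        raise ValueError("labels must contain both classes (+1 and -1)")
    n = y.size
    for view, tab in features.items():
        if len(tab) != n:
            raise ValueError(f"view {view!r} has {len(tab)} rows, labels have {n}")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    w = np.where(y == +1, 0.5 / np.sum(y == +1), 0.5 / np.sum(y == -1)).astype(float)
    model = BoostModel([], [], [])
    for t in range(1, T + 1):
        proposals = []
        for view in sorted(features):  # deterministic order; ties -> "position"
            err, col, thr, pol = _best_stump_for_view(features[view], y, w)
            proposals.append((err, view, col, thr, pol))
        err, view, col, thr, pol = min(proposals, key=lambda p: (p[0], p[1]))
        if err >= 0.5:
            break
        alpha = 0.5 * np.log((1.0 - err) / max(err, _EPS_FLOOR))
        stump = WeakClassifier(view, col, thr, pol, float(alpha), t, float(err))
        model.classifiers.append(stump)
        model.view_trace.append(view)
        h = stump.predict(features[view][col].to_numpy(float))
        w = w * np.exp(-alpha * y * h)
        w = w / w.sum()
        model.weight_history.append(w.copy())
        if err <= 0.0:
            break
    return model


def predict_scores(
    model: BoostModel, features: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Strong-classifier margin F(x) per gene, with per-view partial sums.

    F = F_sequence + F_position exactly; sign(F) is the hard label.
    An empty model scores every gene 0.
    """
    index = next(iter(features.values())).index if features else pd.Index([])
    out = pd.DataFrame(0.0, index=index, columns=["F", "F_sequence", "F_position"])
    for stump in model.classifiers:
        table = features.get(stump.view)
        if table is None or stump.column not in table.columns:
            raise KeyError(
                f"features missing column {stump.column!r} of view {stump.view!r}"
            )
        contrib = stump.alpha * stump.predict(table[stump.column].to_numpy(float))
        out["F"] += contrib
        out[f"F_{stump.view}"] += contrib
    return out


def extract_iteration_scores(
    model: BoostModel, features: Mapping[str, pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-iteration weighted stump outputs, split by the selected view.

    Returns (X, Y): X holds one column per position-selected iteration,
    Y one per sequence-selected iteration; entries are alpha_t * h_t(gene),
    i.e. each column takes the two values ±alpha_t.  A view never selected
    yields an empty block (flagged with a warning).
    """
    if not model.classifiers:
        raise ValueError("model has no trained classifiers")
    index = next(iter(features.values())).index
    blocks: dict[str, dict[str, np.ndarray]] = {"position": {}, "sequence": {}}
    for stump in model.classifiers:
        values = features[stump.view][stump.column].to_numpy(float)
        blocks[stump.view][f"{stump.view[:3]}_t{stump.iteration}"] = (
            stump.alpha * stump.predict(values)
        )
    for view in ("position", "sequence"):
        if not blocks[view]:
            warnings.warn(f"view {view!r} was never selected; its block is empty")
    X = pd.DataFrame(blocks["position"], index=index)
    Y = pd.DataFrame(blocks["sequence"], index=index)
    return X, Y


@dataclass
class CCAResult:
    """Canonical correlations plus correlation-circle loadings."""

    correlations: np.ndarray  # descending, each in [0, 1]
    x_loadings: pd.DataFrame  # variables x first-two-variates correlations
    y_loadings: pd.DataFrame
    ridge: float


def _inv_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.maximum(vals, 1e-12)
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def canonical_correlations(
    X: pd.DataFrame | np.ndarray,
    Y: pd.DataFrame | np.ndarray,
    ridge: float | None = None,
) -> CCAResult:
    """Ridge-regularised CCA of two variable blocks.

    Finds paired linear combinations (variates) of the X and Y columns with
    maximal correlation; a ridge penalty on both block covariances keeps the
    problem well-posed when columns are many or collinear (default 0.1 when
    either block has at least rows/2 columns, else 0).  Loadings are the
    correlations of each variable with the averaged variate (u + v)/2 of the
    first two pairs — the quantities plotted on a correlation circle, where
    an obtuse angle between two variables means negative association.
    """
    X = pd.DataFrame(X).astype(float)
    Y = pd.DataFrame(Y).astype(float)
    n = len(X)
    if n < 3 or len(Y) != n:
        raise ValueError("need >= 3 rows and matching row counts")
    if X.shape[1] < 1 or Y.shape[1] < 1:
        raise ValueError("each block needs at least one column")
    for df in (X, Y):
        stds = df.std(ddof=1)
        for col, s in stds.items():
            if s < 1e-12:
                raise ValueError(f"constant column {col!r}")
    if ridge is None:
        ridge = 0.1 if max(X.shape[1], Y.shape[1]) >= n / 2 else 0.0
    Xc = (X - X.mean()) / X.std(ddof=1)
    Yc = (Y - Y.mean()) / Y.std(ddof=1)
    Cxx = Xc.T.to_numpy() @ Xc.to_numpy() / (n - 1) + ridge * np.eye(X.shape[1])
    Cyy = Yc.T.to_numpy() @ Yc.to_numpy() / (n - 1) + ridge * np.eye(Y.shape[1])
    Cxy = Xc.T.to_numpy() @ Yc.to_numpy() / (n - 1)
    Wx, Wy = _inv_sqrt(Cxx), _inv_sqrt(Cyy)
    U, s, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    corrs = np.clip(s, 0.0, 1.0)
    k = min(2, s.size)
    a = Wx @ U[:, :k]  # canonical coefficient vectors
    b = Wy @ Vt.T[:, :k]
    u = Xc.to_numpy() @ a
    v = Yc.to_numpy() @ b
    z = (u + v) / 2.0
    if k == 1:
        z = np.hstack([z, np.zeros_like(z)])

    def _loadings(block: pd.DataFrame) -> pd.DataFrame:
        vals = block.to_numpy()
        out = np.zeros((block.shape[1], 2))
        for j in range(min(2, z.shape[1])):
            zj = z[:, j]
            sd = zj.std(ddof=1)
            if sd < 1e-12:
                continue
            zjc = (zj - zj.mean()) / sd
            out[:, j] = (vals * zjc[:, None]).mean(axis=0) * n / (n - 1)
        return pd.DataFrame(out, index=block.columns, columns=["variate1", "variate2"])

    return CCAResult(corrs, _loadings(Xc), _loadings(Yc), float(ridge))


# ---------------------------------------------------------------------------
# model persistence (structured text, versioned)
# ---------------------------------------------------------------------------


def save_model(model: BoostModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "view_trace": model.view_trace,
        "classifiers": [asdict(c) for c in model.classifiers],
        "weight_history": [w.tolist() for w in model.weight_history],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> BoostModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('format_version')}")
    classifiers = [WeakClassifier(**c) for c in payload["classifiers"]]
    history = [np.asarray(w) for w in payload["weight_history"]]
    return BoostModel(classifiers, history, list(payload["view_trace"]))
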