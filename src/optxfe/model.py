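"""Model/Results interface tying the whole pipeline together.

:class:`OpTXfe` is constructed from data (raw segments or a precomputed
feature matrix); :meth:`OpTXfe.fit` runs NCA weighting, the iterative
cumulative-weight selection, the requested cross-validation protocols and
the symbolic interpretation, and returns an :class:`OpTXfeResults` carrying
the selected features, per-protocol confusion matrices and metrics, the
DLob report and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cwinca, dlob, evaluation
from .features import extract_feature_matrix, split_feature_frame
from .opt import OperatorBank

__all__ = ["OpTXfe", "OpTXfeResults"]


class OpTXfe:
    """Operational-Transformer explainable feature-engineering model.

    Parameters
    ----------
    X, y, subjects
        Feature matrix (segments x features), class labels (1 = epilepsy,
        2 = control) and per-segment subject identifiers.
    cn
        Channel count of the source montage (needed to invert feature
        indices into channel pairs).
    lut
        Positional channel -> lobe-symbol table; defaults to the bundled
        35-channel table when ``cn == 35``.
    t_low, t_high
        Cumulative-weight thresholds of the selection loop.
    step
        Candidate-size stride of the selection loop.
    scale_features
        Z-score the feature matrix before selection and classification.
        Off by default: transition counts share one natural scale.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        subjects: np.ndarray,
        cn: int,
        lut=None,
        t_low: float = 0.5,
        t_high: float = 0.99,
        step: int = 1,
        knn_k: int = 1,
        scale_features: bool = False,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        if scale_features:
            sd = self.X.std(axis=0)
            sd[sd == 0] = 1.0
            self.X = (self.X - self.X.mean(axis=0)) / sd
        self.scale_features = bool(scale_features)
        self.y = np.asarray(y)
        self.subjects = np.asarray(subjects)
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise ValueError("X, y and subjects must have equal length")
        self.cn = int(cn)
        if self.X.shape[1] % (self.cn * self.cn) != 0:
            raise ValueError(
                f"feature count {self.X.shape[1]} is not a multiple of cn^2 = {self.cn ** 2}"
            )
        if lut is not None:
            self.lut = dlob.validate_lut(lut, self.cn)
        elif self.cn == len(dlob.DEFAULT_LUT):
            self.lut = dlob.DEFAULT_LUT
        else:
            self.lut = None  # symbolic stage unavailable without a table
        self.t_low, self.t_high, self.step = t_low, t_high, step
        self.knn_k = int(knn_k)

    @classmethod
    def from_segments(
        cls, segments, bank: OperatorBank | None = None, lut=None, **kwargs
    ) -> "OpTXfe":
        """Build the model from raw segments by running feature extraction."""
        segments = list(segments)
        frame = extract_feature_matrix(segments, bank)
        X, y, subjects = split_feature_frame(frame)
        return cls(X, y, subjects, cn=segments[0].data.shape[1], lut=lut, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, cn: int, label_col: str = "label",
        subject_col: str = "subject_id", lut=None, **kwargs,
    ) -> "OpTXfe":
        """Build the model from a feature DataFrame with label/subject columns."""
        X = df.drop(columns=[label_col, subject_col]).to_numpy(dtype=float)
        return cls(X, df[label_col].to_numpy(), df[subject_col].to_numpy(), cn=cn, lut=lut, **kwargs)

    def fit(
        self,
        protocols: tuple[str, ...] = ("kfold", "loso"),
        folds: int = 10,
        seed: int = 0,
        nested: bool = False,
    ) -> "OpTXfeResults":
        """Select features, evaluate the classifier and build the explanation.

        With ``nested=True`` the selection is re-run inside each training
        fold of every protocol, so the held-out data never influences which
        features are kept.  This is the unbiased (and for subject-independent
        reporting, recommended) estimator; the default ``nested=False``
        mirrors the simpler select-once-then-validate practice, whose
        reported accuracy inherits an optimistic selection bias.
        """
        selection = cwinca.select(
            self.X, self.y, t_low=self.t_low, t_high=self.t_high, step=self.step,
            seed=seed, folds=min(folds, len(self.y)),
        )
        cms: dict[str, evaluation.ConfusionMatrix] = {}
        if "kfold" in protocols:
            if nested:
                cms["kfold"] = self._nested_kfold(folds, seed)
            else:
                cms["kfold"] = evaluation.kfold_cv(selection.SX, self.y, folds=folds, seed=seed, k=self.knn_k)
        if "loso" in protocols:
            if nested:
                cms["loso"] = self._nested_loso(seed)
            else:
                cms["loso"] = evaluation.loso_cv(selection.SX, self.y, self.subjects, k=self.knn_k)
        reports = {name: evaluation.metrics(cm) for name, cm in cms.items()}
        dlob_rep = None
        if self.lut is not None and selection.nsf > 0:
            symbols = dlob.build_dlob_string(selection.ind, self.lut)
            dlob_rep = dlob.dlob_report(symbols)
        return OpTXfeResults(
            model=self, selection=selection, confusion=cms, metrics=reports,
            dlob=dlob_rep, seed=seed, folds=folds,
        )

    def _fit_fold(self, train_mask: np.ndarray, seed: int, folds: int = 10) -> np.ndarray:
        sel = cwinca.select(
            self.X[train_mask], self.y[train_mask], t_low=self.t_low,
            t_high=self.t_high, step=self.step, seed=seed, folds=folds,
        )
        cols = sel.ind - 1
        return evaluation.knn_predict(
            self.X[train_mask][:, cols], self.y[train_mask],
            self.X[~train_mask][:, cols], k=self.knn_k,
        )

    def _nested_kfold(self, folds: int, seed: int) -> evaluation.ConfusionMatrix:
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        y_pred = np.empty_like(self.y)
        for tr, te in skf.split(self.X, self.y):
            mask = np.zeros(len(self.y), dtype=bool)
            mask[tr] = True
            y_pred[te] = self._fit_fold(mask, seed, folds=folds)
        return evaluation.ConfusionMatrix.from_predictions(self.y, y_pred)

    def _nested_loso(self, seed: int) -> evaluation.ConfusionMatrix:
        y_pred = np.empty_like(self.y)
        for s in np.unique(self.subjects):
            te = self.subjects == s
            y_pred[te] = self._fit_fold(~te, seed)
        return evaluation.ConfusionMatrix.from_predictions(self.y, y_pred)


@dataclass
class OpTXfeResults:
    """Fitted-pipeline results: selection, validation metrics, explanation."""

    model: OpTXfe
    selection: cwinca.SelectionResult
    confusion: dict[str, evaluation.ConfusionMatrix]
    metrics: dict[str, evaluation.MetricsReport]
    dlob: dlob.DlobReport | None
    seed: int
    folds: int

    def summary(self) -> str:
        """Human-readable report in the spirit of statsmodels summaries."""
        lines = []
        add = lines.append
        add("Operational-Transformer XFE results")
        add("=" * 55)
        add(f"segments: {len(self.model.y)}   features: {self.model.X.shape[1]}"
            f"   channels: {self.model.cn}")
        add(f"selection range: k = {self.selection.start_k}..{self.selection.stop_k}"
            f" (step {self.model.step}); selected nsf = {self.selection.nsf}")
        add("-" * 55)
        add(f"{'metric':<22}" + "".join(f"{p:>14}" for p in self.metrics))
        names = ["accuracy", "sensitivity", "specificity", "geometric_mean"]
        for nm in names:
            row = f"{nm:<22}"
            for rep in self.metrics.values():
                row += f"{getattr(rep, nm):>14.2f}"
            add(row)
        if self.dlob is not None:
            add("-" * 55)
            add(f"DLob symbols: {len(self.dlob.symbols)}   "
                f"entropy: {self.dlob.entropy_bits:.4f} bits   "
                f"complexity ratio: {self.dlob.complexity_ratio_percent:.2f}%")
            top = dlob.ALPHABET[int(np.argmax(self.dlob.histogram))]
            add(f"dominant symbol: {top} ({int(self.dlob.histogram.max())}/{len(self.dlob.symbols)})")
        add("=" * 55)
        return "\n".join(lines)

    def plot_dlob_histogram(self, ax=None):
        if self.dlob is None:
            raise ValueError("no DLob report (no LUT for this montage)")
        return dlob.plot_histogram(self.dlob, ax=ax)

    def plot_connectome(self, ax=None, min_count: int = 1):
        if self.dlob is None:
            raise ValueError("no DLob report (no LUT for this montage)")
        return dlob.plot_connectome(self.dlob, ax=ax, min_count=min_count)
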