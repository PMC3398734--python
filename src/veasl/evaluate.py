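"""Scoring decoders against ground truth: flow RMSE and artery-detection ROC.

RMSE is the root of the mean squared error over all voxel-artery pairs of a
dataset (static plane excluded); the batch summary is the median RMSE across
datasets.  ROC curves score artery identification: a voxel-artery pair is a
positive if its true contribution is nonzero, predictions threshold the
estimated contribution magnitude, and rates are pooled over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labelling import ModulationModel
from .model import VEASLModel
from .simulate import SimulatedDataset

__all__ = ["MethodScore", "rmse_flow", "roc_curve", "compare_methods",
           "MethodComparison"]


def rmse_flow(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square error between estimated and true flow contributions.

    ``estimate`` and ``truth`` are (V, M) artery planes; complex estimates
    are compared by magnitude.
    """
    est = np.asarray(estimate)
    tru = np.asarray(truth)
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {tru.shape}")
    if np.iscomplexobj(est):
        est = np.abs(est)
    return float(np.sqrt(np.mean((est - tru) ** 2)))


@dataclass
class MethodScore:
    """Per-method evaluation: RMSE distribution and pooled ROC."""

    method: str
    rmse: list[float] = field(default_factory=list)
    fpr: np.ndarray | None = None
    tpr: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    auc: float = np.nan

    @property
    def median_rmse(self) -> float:
        return float(np.median(self.rmse))


def roc_curve(estimates, truths, n_thresholds: int = 200):
    """Pooled ROC over a batch of estimated/true flow maps.

    Thresholds sweep 0 to the batch maximum (log-spaced above zero); returns
    ``(fpr, tpr, thresholds, auc)`` with AUC by trapezoid after sorting by
    FPR.  Raises if the truth contains no positives.
    """
    score = np.concatenate([np.abs(np.asarray(e)).ravel() for e in estimates])
    pos = np.concatenate([np.asarray(t).ravel() != 0 for t in truths])
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0:
        raise ValueError("truth contains no positive voxel-artery pairs")
    if n_neg == 0:
        raise ValueError("truth contains no negative voxel-artery pairs")
    top = score.max()
    if top <= 0:
        taus = np.array([0.0])
    else:
        taus = np.concatenate(
            [[0.0], np.geomspace(max(top * 1e-6, 1e-12), top, n_thresholds - 1)]
        )
    tpr = np.array([(score[pos] > t).mean() for t in taus])
    fpr = np.array([(score[~pos] > t).mean() for t in taus])
    order = np.lexsort((tpr, fpr))
    f, t = fpr[order], tpr[order]
    # close the curve at (0,0) and (1,1) for the trapezoid
    f = np.concatenate([[0.0], f, [1.0]])
    t = np.concatenate([[0.0], t, [1.0]])
    auc = float(np.trapezoid(t, f))
    return fpr, tpr, taus, auc


def _decode(ds: SimulatedDataset, method: str, apc: int,
            model: ModulationModel | None, mcmc_kwargs=None):
    """Run one decoder on one dataset; returns (V, M) artery estimates."""
    arts = ds.arteries
    if method == "MIt":
        arteries = arts  # true locations and speeds
    else:
        # planning information only: planned locations, nominal 30 cm/s
        arteries = type(arts)(
            names=list(arts.names), planned=arts.planned.copy(),
            current=arts.planned.copy(),
            speeds=np.full(arts.n_arteries, 30.0),
        )
    m = VEASLModel(ds.data, ds.config.scheme(), arteries,
                   modulation=model, apc=apc)
    if method in ("MI", "MIt"):
        res = m.fit("MI")
    elif method.endswith("_MCMC"):
        res = m.fit_mcmc(method[:-5], **(mcmc_kwargs or {}))
    else:
        res = m.fit(method)
    return res.artery_flow(frame=0)


@dataclass
class MethodComparison:
    """Tabulated batch comparison across decoders."""

    table: pd.DataFrame  # per-dataset rows: method, apc, n_cycles, dataset, rmse
    scores: dict  # (method, apc) -> MethodScore

    def medians(self) -> pd.DataFrame:
        return (
            self.table.groupby(["method", "apc"])["rmse"]
            .median()
            .rename("median_rmse")
            .reset_index()
        )

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    def plot_rmse(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        med = self.medians()
        labels = [f"{m} ({a}APC)" for m, a in zip(med["method"], med["apc"])]
        ax.bar(labels, med["median_rmse"])
        ax.set_ylabel("median RMSE")
        ax.tick_params(axis="x", rotation=60)
        return ax

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for (method, apc), sc in self.scores.items():
            if sc.fpr is None:
                continue
            order = np.argsort(sc.fpr)
            ax.plot(sc.fpr[order], sc.tpr[order],
                    label=f"{method} ({apc}APC), AUC={sc.auc:.3f}")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        return ax


def compare_methods(datasets, methods=("MI", "MIt", "BI", "BT3"),
                    apc=(2,), model: ModulationModel | None = None,
                    mcmc_kwargs=None, with_roc: bool = True) -> MethodComparison:
    """Decode every dataset with every method and tabulate RMSE and ROC.

    Matrix-inversion methods ignore the arteries-per-class setting (recorded
    with apc=0 in the table).  A decoder failure on a dataset is recorded as
    a missing value, not raised.
    """
    rows = []
    scores: dict = {}
    for method in methods:
        apcs = (0,) if method in ("MI", "MIt") else tuple(apc)
        for L in apcs:
            ests, truths = [], []
            for i, ds in enumerate(datasets):
                try:
                    est = _decode(ds, method, L or 1, model, mcmc_kwargs)
                except Exception as err:  # recorded, not fatal
                    rows.append(dict(method=method, apc=L, dataset=i,
                                     n_cycles=ds.config.n_cycles,
                                     rmse=np.nan, error=str(err)))
                    continue
                rows.append(dict(method=method, apc=L, dataset=i,
                                 n_cycles=ds.config.n_cycles,
                                 rmse=rmse_flow(est, ds.truth_flow), error=""))
                ests.append(np.abs(est))
                truths.append(ds.truth_flow)
            sc = MethodScore(method=method,
                             rmse=[r["rmse"] for r in rows
                                   if r["method"] == method and r["apc"] == L
                                   and np.isfinite(r["rmse"])])
            if with_roc and ests:
                sc.fpr, sc.tpr, sc.thresholds, sc.auc = roc_curve(ests, truths)
            scores[(method, L)] = sc
    return MethodComparison(table=pd.DataFrame(rows), scores=scores)
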