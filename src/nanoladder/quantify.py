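"""Expression matrices, detection efficiency, qPCR fold change, and
cell-type discrimination from decoded spot tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "build_expression_matrix",
    "estimate_detection_efficiency",
    "fold_change_ddct",
    "discriminate_cell_types",
]


def build_expression_matrix(
    decoded: pd.DataFrame,
    genes: list[str] | None = None,
    cells: list | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate decoded spots into a genes x cells count matrix.

    Rejected spots (``assigned == "REJECT"``) are excluded from the matrix
    but reported as a per-cell series.  Column sums of the matrix equal the
    per-cell decoded totals by construction.
    """
    if decoded.empty:
        return (
            pd.DataFrame(dtype=int, index=pd.Index(genes or [], name="gene_id")),
            pd.Series(dtype=int),
        )
    is_reject = decoded["assigned"] == "REJECT"
    kept = decoded[~is_reject]
    matrix = kept.groupby(["assigned", "cell_id"]).size().unstack(fill_value=0)
    if genes is not None:
        matrix = matrix.reindex(index=genes, fill_value=0)
    if cells is not None:
        matrix = matrix.reindex(columns=cells, fill_value=0)
    matrix.index.name = "gene_id"
    rejects = decoded[is_reject].groupby("cell_id").size()
    if cells is not None:
        rejects = rejects.reindex(cells, fill_value=0)
    return matrix.astype(int), rejects.astype(int)


def estimate_detection_efficiency(
    observed_counts, reference_mean_copies: float, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Detection efficiency as observed/reference with a Wilson interval.

    ``observed_counts`` are per-cell detected copy numbers for one gene;
    ``reference_mean_copies`` is the independently known per-cell mean (e.g.
    from RT-qPCR).  The interval treats the pooled observed count as a
    binomial draw out of ``n_cells * reference_mean`` trials.
    """
    observed = np.asarray(observed_counts, dtype=float)
    if reference_mean_copies <= 0:
        raise ValueError("reference mean copies must be positive")
    if observed.size == 0:
        raise ValueError("no observed counts")
    successes = float(observed.sum())
    trials = max(int(round(reference_mean_copies * observed.size)), 1)
    eff = float(observed.mean() / reference_mean_copies)
    lo, hi = proportion_confint(min(successes, trials), trials, alpha=alpha, method="wilson")
    return eff, (float(lo), float(hi))


def fold_change_ddct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    test_sample: str,
    calibrator_sample: str,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the test sample minus the same
    difference in the calibrator sample; replicate Ct values are averaged
    first.  Returns 2**(-ddCt).
    """
    means = ct.groupby(["sample_id", "gene_id"])["ct"].mean()

    def get(sample: str, gene: str) -> float:
        try:
            return float(means.loc[(sample, gene)])
        except KeyError:
            raise ValueError(f"missing Ct values for sample={sample!r}, gene={gene!r}")

    ddct = (get(test_sample, target_gene) - get(test_sample, reference_gene)) - (
        get(calibrator_sample, target_gene) - get(calibrator_sample, reference_gene)
    )
    return float(2.0 ** (-ddct))


def discriminate_cell_types(
    matrix: pd.DataFrame, labels: pd.Series
) -> tuple[pd.Series, pd.DataFrame, float]:
    """Leave-one-out nearest-centroid classification on log1p counts.

    ``matrix`` is genes x cells; ``labels`` maps cell ids (matrix columns) to
    class names.  Returns (predicted labels, confusion table, accuracy).
    Nearest-centroid on log-counts is deterministic and has no
    hyperparameters; distance ties break toward the alphabetically first
    class.
    """
    cells = [c for c in matrix.columns if c in labels.index]
    if not cells:
        raise ValueError("no labelled cells in the matrix")
    y = labels.loc[cells]
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes to discriminate")
    if (y.value_counts() < 2).any():
        raise ValueError("need at least two cells per class")
    X = np.log1p(matrix[cells].to_numpy(dtype=float)).T  # cells x genes

    predicted = []
    y_arr = y.to_numpy()
    for i in range(len(cells)):
        keep = np.arange(len(cells)) != i
        cents = []
        for cls in classes:
            members = keep & (y_arr == cls)
            if not members.any():  # held-out cell was the sole member
                cents.append(np.full(X.shape[1], np.inf))
            else:
                cents.append(X[members].mean(axis=0))
        d = [np.linalg.norm(X[i] - c) for c in cents]
        predicted.append(classes[int(np.argmin(d))])
    predicted = pd.Series(predicted, index=cells, name="predicted")

    confusion = pd.crosstab(y.rename("true"), predicted).reindex(
        index=classes, columns=classes, fill_value=0
    )
    accuracy = float((predicted.to_numpy() == y_arr).mean())
    return predicted, confusion, accuracy
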