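"""Pairwise Pearson correlation of propensity scales over peptide fragments.

Two scales are compared by concatenating all fragments of one class
(epitopes, say) into a single residue string, replacing each residue by
its value under scale *i* to get one series and under scale *j* to get a
second, and correlating the two series over residue positions.  Strongly
correlated scales carry redundant information and are unlikely to add
discriminating power when combined; weakly correlated pairs may.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import encode_value_series
from .preprocess import Dataset
from .scales import NormalizedScale


@dataclass
class CorrelationMatrix:
    """Symmetric scale-by-scale Pearson matrix for one peptide class."""

    values: pd.DataFrame  # square, index/columns = scale names
    class_label: str
    n_residues: int

    def __getitem__(self, pair: tuple[int, int]) -> float:
        """Entry by 1-based scale indices."""
        i, j = pair
        return float(self.values.iloc[i - 1, j - 1])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    def summary(self) -> str:
        return (
            f"Pearson correlations over {self.n_residues} concatenated residues "
            f"({self.class_label})\n" + self.values.round(3).to_string()
        )


def propensity_correlations(
    fragments: Sequence[str],
    scales: Sequence[NormalizedScale],
    class_label: str = "epitope",
) -> CorrelationMatrix:
    """Pearson correlation between every pair of scales over the fragments.

    A scale whose value series has zero variance over the residues present
    yields undefined correlations; those entries are reported as NaN with
    a warning (the diagonal entry of such a scale is NaN too).
    """
    series = np.vstack([encode_value_series(fragments, s) for s in scales])
    if series.shape[1] < 2:
        raise ValueError("need at least 2 residues in total to correlate")
    sd = series.std(axis=1)
    degenerate = np.flatnonzero(sd == 0.0)
    if degenerate.size:
        warnings.warn(
            "zero-variance value series for scale(s) "
            f"{[scales[i].name for i in degenerate]}; entries reported as NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(series)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry against BLAS rounding
    np.fill_diagonal(corr, 1.0)   # var/sqrt(var)^2 can round away from exact 1
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    names = [s.name for s in scales]
    return CorrelationMatrix(
        values=pd.DataFrame(corr, index=names, columns=names),
        class_label=class_label,
        n_residues=series.shape[1],
    )


def dataset_correlations(
    dataset: Dataset, scales: Sequence[NormalizedScale]
) -> dict[str, CorrelationMatrix]:
    """One correlation matrix per class (epitope and non-epitope) of a dataset."""
    out = {}
    for label, tag in ((1, "epitope"), (0, "non-epitope")):
        frags = dataset.subset(label).sequences
        if frags:
            out[tag] = propensity_correlations(frags, scales, class_label=tag)
    return out
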