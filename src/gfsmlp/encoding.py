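"""Peptide encodings: grouped propensity vectors, one-hot vectors, value series.

The propensity encoding maps a 20-mer onto ``n_scales * 20`` reals laid out
group-major: the first 20 entries are the positions 1..20 under scale 1,
the next 20 under scale 2, and so on.  With the eight bundled scales this
is the familiar 160-dimensional representation.  Group-major layout means a
single attenuator gate masks one contiguous slice of the vector.

The binary (identity) encoding is the standard one-hot code: each residue
occupies a 20-slot block with a single 1 marking its identity, 400 entries
per 20-mer.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .preprocess import PEPTIDE_LENGTH, Dataset, validate_peptide
from .scales import STANDARD_RESIDUES, NormalizedScale

_RESIDUE_INDEX = {res: i for i, res in enumerate(STANDARD_RESIDUES)}


def group_slices(n_scales: int, length: int = PEPTIDE_LENGTH) -> list[slice]:
    """Contiguous index ranges of the groups tiling [0, n_scales*length)."""
    return [slice(i * length, (i + 1) * length) for i in range(n_scales)]


def encode_propensity(
    peptide: str, scales: Sequence[NormalizedScale], length: int = PEPTIDE_LENGTH
) -> np.ndarray:
    """Encode a peptide as a grouped propensity vector (group-major layout).

    Entry ``i*length + p`` is the normalised value of the residue at
    position ``p`` under scale ``i``.  Raises on wrong length or
    non-standard residues.
    """
    seq = validate_peptide(peptide, length)
    out = np.empty(len(scales) * length)
    for i, scale in enumerate(scales):
        vals = scale.values
        out[i * length : (i + 1) * length] = [vals[res] for res in seq]
    return out


def encode_binary(peptide: str, length: int = PEPTIDE_LENGTH) -> np.ndarray:
    """One-hot identity encoding: ``length`` blocks of 20, one 1 per block."""
    seq = validate_peptide(peptide, length)
    out = np.zeros(length * 20)
    for p, res in enumerate(seq):
        out[p * 20 + _RESIDUE_INDEX[res]] = 1.0
    return out


def encode_value_series(fragments: Sequence[str], scale: NormalizedScale) -> np.ndarray:
    """Concatenate fragments and replace each residue by its scale value.

    This is the series used for correlating two propensity scales over a
    set of epitope (or non-epitope) fragments; fragments may be any length.
    """
    if len(fragments) == 0:
        raise ValueError("encode_value_series requires at least one fragment")
    vals = scale.values
    series = []
    for frag in fragments:
        seq = frag.strip().upper()
        if not seq:
            raise ValueError("empty fragment")
        try:
            series.extend(vals[res] for res in seq)
        except KeyError as exc:
            raise ValueError(f"non-standard residue {exc.args[0]!r} in {seq!r}") from None
    return np.asarray(series)


def encode_dataset(
    dataset: Dataset,
    scales: Sequence[NormalizedScale] | None = None,
    encoding: str = "propensity",
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every record; returns (X, y).

    ``encoding`` is ``"propensity"`` (needs ``scales``) or ``"binary"``.
    """
    if encoding == "propensity":
        if scales is None:
            from .scales import builtin_normalized_scales

            scales = builtin_normalized_scales()
        X = np.stack([encode_propensity(s, scales) for s in dataset.sequences])
    elif encoding == "binary":
        X = np.stack([encode_binary(s) for s in dataset.sequences])
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return X, dataset.labels


def encoded_columns(scales: Sequence[NormalizedScale], length: int = PEPTIDE_LENGTH) -> list[str]:
    """Column names 'scale:position' matching the group-major layout."""
    return [f"{s.name}:{p + 1}" for s in scales for p in range(length)]


def write_encoded_tsv(X: np.ndarray, y: np.ndarray, columns: Sequence[str], path) -> None:
    import pandas as pd

    df = pd.DataFrame(X, columns=list(columns))
    df.insert(0, "label", y)
    df.to_csv(path, sep="\t", index=False)
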