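"""Amino-acid propensity scales and their normalisation.

A propensity scale assigns one real value to each of the 20 standard amino
acids, quantifying a physico-chemical tendency such as hydrophilicity or
beta-turn preference.  Eight widely used scales are bundled with the package
(see ``data/propensity_scales.tsv`` for sources); users can substitute their
own tables in the same three-column TSV format.

Before a scale is used as an encoding it is rescaled to the interval
[-1, 1] with the symmetric min-max map

    v' = 2 * (v - Rmin) / (Rmax - Rmin) - 1

where ``Rmax`` and ``Rmin`` are the largest and smallest of the 20 raw
values.  The map is affine, so the rank order of residues is preserved and
the result is invariant to any positive affine transform of the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_SET = frozenset(STANDARD_RESIDUES)

#: Names of the eight bundled scales, in their conventional numbering order
#: (1 = hydrophilicity ... 8 = beta-turn).
BUILTIN_SCALE_NAMES = (
    "hydrophilicity_parker",
    "accessibility_emini",
    "flexibility_karplus",
    "surface_janin",
    "polarity_ponnuswamy",
    "turns_pellequer",
    "antigenicity_kolaskar",
    "beta_turn_chou",
)


class DegenerateScaleError(ValueError):
    """Raised when a scale is constant (Rmax == Rmin) and cannot be normalised."""


@dataclass(frozen=True)
class PropensityScale:
    """A named mapping from the 20 standard residues to raw real values."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = _RESIDUE_SET - set(self.values)
        extra = set(self.values) - _RESIDUE_SET
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must define exactly the 20 standard residues "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )

    @property
    def r_max(self) -> float:
        return max(self.values.values())

    @property
    def r_min(self) -> float:
        return min(self.values.values())

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclass(frozen=True)
class NormalizedScale:
    """A propensity scale rescaled so its values span exactly [-1, 1]."""

    name: str
    values: Mapping[str, float]

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def normalize_scale(scale: PropensityScale) -> NormalizedScale:
    """Rescale a raw propensity scale to [-1, 1] by symmetric min-max.

    The residue with the largest raw value maps to +1, the smallest to -1,
    and the midpoint (Rmax+Rmin)/2 to 0.

    Raises
    ------
    DegenerateScaleError
        If all 20 raw values are equal, so no affine map can spread them
        over [-1, 1].
    """
    r_max, r_min = scale.r_max, scale.r_min
    if r_max == r_min:
        raise DegenerateScaleError(
            f"scale {scale.name!r} is constant ({r_max}); cannot normalise"
        )
    span = r_max - r_min
    values = {
        res: 2.0 * (val - r_min) / span - 1.0 for res, val in scale.values.items()
    }
    return NormalizedScale(name=scale.name, values=values)


def load_scales_tsv(path: str | Path) -> list[PropensityScale]:
    """Read propensity scales from a three-column TSV (scale, residue, value).

    Lines starting with ``#`` are comments.  Scales appear in first-seen
    order.  Each scale must define all 20 standard residues exactly once.
    """
    tables: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            name, residue, value = parts[0], parts[1].upper(), float(parts[2])
            table = tables.setdefault(name, {})
            if residue in table:
                raise ValueError(f"{path}:{lineno}: duplicate residue {residue!r} in {name!r}")
            table[residue] = value
    return [PropensityScale(name=name, values=vals) for name, vals in tables.items()]


def builtin_scales() -> list[PropensityScale]:
    """The eight bundled propensity scales, in numbering order 1-8.

    Order: hydrophilicity (Parker), accessibility (Emini), flexibility
    (Karplus-Schulz), surface exposure (Janin), polarity (Ponnuswamy),
    turns (Pellequer), antigenicity (Kolaskar), beta-turn (Chou-Fasman).
    """
    with resources.as_file(
        resources.files("gfsmlp").joinpath("data/propensity_scales.tsv")
    ) as path:
        scales = load_scales_tsv(path)
    by_name = {s.name: s for s in scales}
    return [by_name[name] for name in BUILTIN_SCALE_NAMES]


def builtin_normalized_scales() -> list[NormalizedScale]:
    """``builtin_scales`` with each scale normalised to [-1, 1]."""
    return [normalize_scale(s) for s in builtin_scales()]


def normalize_all(scales: Iterable[PropensityScale]) -> list[NormalizedScale]:
    return [normalize_scale(s) for s in scales]
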