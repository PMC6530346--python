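"""Zero replacement and spot-class bookkeeping ahead of normalization.

Exact zeros in the exported matrix come from detection limits of the
fluorescent dyes/scanner and from rounding, not from missing spots, and
they block the log transform the downstream model requires.  They are
replaced by class-specific floor values:

* sample channel: the lowest *positive* value observed anywhere in the
  sample channel (one global floor);
* internal-standard channel: the lowest positive value observed for the
  same spot across gels (the standard is one pool, so a spot's IPS
  level is a property of the spot).

"Lowest observed value" is read as lowest positive value: the literal
minimum of a matrix that contains zeros would be zero and replace
nothing, defeating the stated purpose of enabling log transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationTable, SpotClass, SpotMatrix, ValidationError, CHANNELS


@dataclass(frozen=True)
class ZeroPolicy:
    """Zero-replacement rules (single implemented value per channel)."""

    sample_rule: str = "global_min_positive"
    ips_rule: str = "spotwise_min_positive"

    def __post_init__(self) -> None:
        if self.sample_rule != "global_min_positive":
            raise ValidationError(f"unknown sample_rule {self.sample_rule!r}")
        if self.ips_rule != "spotwise_min_positive":
            raise ValidationError(f"unknown ips_rule {self.ips_rule!r}")


def replace_zeros(matrix: SpotMatrix, policy: ZeroPolicy = ZeroPolicy()) -> SpotMatrix:
    """Return a strictly positive copy of ``matrix``.

    Idempotent; never decreases a value and never alters a positive one.
    Raises if the sample channel has no positive value, or if some spot
    has only zeros on the IPS channel (no defined replacement).
    """
    sample = matrix.sample.copy()
    ips = matrix.ips.copy()

    positive = sample[sample > 0]
    if positive.size == 0:
        raise ValidationError("sample channel contains no positive value")
    sample[sample == 0] = positive.min()

    for s in range(ips.shape[0]):
        row = ips[s]
        zeros = row == 0
        if zeros.any():
            pos = row[row > 0]
            if pos.size == 0:
                raise ValidationError(
                    f"spot {matrix.spot_ids[s]!r}: all IPS values are zero, "
                    "no replacement value exists"
                )
            row[zeros] = pos.min()
    return SpotMatrix(list(matrix.spot_ids), list(matrix.gel_ids), sample, ips)


def compute_class_proportions(
    matrix: SpotMatrix, annotation: AnnotationTable
) -> pd.DataFrame:
    """Spot counts and relative summed volumes per spot class.

    Returns one row per class with columns ``n_spots``,
    ``count_fraction`` and ``volume_fraction_<channel>``; counts sum to
    the number of spots and each volume-fraction column sums to 1.
    """
    annotation.validate_against(matrix)
    rows = []
    totals = {ch: matrix.channel(ch).sum() for ch in CHANNELS}
    for cls in SpotClass:
        mask = annotation.class_mask(matrix.spot_ids, cls)
        row = {
            "spot_class": cls.value,
            "n_spots": int(mask.sum()),
            "count_fraction": float(mask.sum() / matrix.n_spots),
        }
        for ch in CHANNELS:
            total = totals[ch]
            row[f"volume_fraction_{ch}"] = (
                float(matrix.channel(ch)[mask].sum() / total) if total > 0 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("spot_class")
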