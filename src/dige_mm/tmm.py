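"""Class-restricted TMM normalization with CPM-style log2 scaling.

This is the methodological core of the pipeline.  In a 2D-DiGE map of
a tissue surface, high-abundance plasma-type spots can make up a large
and *sample-dependent* share of the total volume on a gel.  Any
normalization that divides by the full-column total therefore couples
every cellular spot's relative abundance to the sample's plasma
content.  The remedy mirrors library-size normalization in RNA-seq:

1. the **effective library size** of a gel x channel column is the sum
   of volumes over *cellular-type spots only*;
2. a **trimmed mean of M-values** (TMM) scaling factor is computed per
   column against a reference column, again using only cellular spots,
   exactly as in the published TMM algorithm: per-spot log-ratios
   ``M_s = log2((y_sk/N_k)/(y_sr/N_r))`` and average abundances
   ``A_s = (log2(y_sk/N_k) + log2(y_sr/N_r))/2`` are doubly trimmed
   (default 30% per tail of M, 5% per tail of A, rank-based) and the
   surviving M-values averaged with precision weights ``1/v_s`` where
   ``v_s = (N_k - y_sk)/(N_k y_sk) + (N_r - y_sr)/(N_r y_sr)``;
   the reference is the column whose 75th percentile of ``y/N`` is
   closest to the mean of those percentiles (lowest index on ties);
   factors are rescaled to geometric mean 1;
3. every spot (including plasma and unidentified ones) is expressed
   **per million of effective library**: ``log2(y/(N*f) * 1e6 + prior)``
   with a small additive prior keeping the transform finite.

Because steps 1-2 use cellular spots only, rescaling plasma-spot
volumes in any column leaves every cellular spot's normalized value
exactly unchanged.  The sample and IPS channels are normalized
independently; the IPS is one pool, so its factors sit near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import AnnotationTable, SpotClass, SpotMatrix, ValidationError, CHANNELS


class NormalizationError(ValueError):
    """Raised when no valid scaling can be computed."""


def compute_library_sizes(matrix: SpotMatrix, annotation: AnnotationTable) -> dict:
    """Per-column totals over cellular-type spots, for each channel.

    Returns ``{"sample": (n_gels,), "ips": (n_gels,)}``.  Requires a
    strictly positive matrix (run zero replacement first) and at least
    one cellular spot.
    """
    cellular = annotation.class_mask(matrix.spot_ids, SpotClass.cellular)
    if not cellular.any():
        raise NormalizationError("no cellular-type spots; library sizes undefined")
    for ch in CHANNELS:
        if (matrix.channel(ch) <= 0).any():
            raise ValidationError(
                f"{ch} channel contains nonpositive values; run replace_zeros first"
            )
    return {ch: matrix.channel(ch)[cellular].sum(axis=0) for ch in CHANNELS}


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
    min_kept: int,
) -> float:
    """TMM factor of one column against the reference (published algorithm)."""
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() < min_kept:
        raise NormalizationError(
            f"only {int(keep.sum())} cellular spots survive trimming "
            f"(minimum {min_kept}); use smaller trim fractions"
        )
    return float(2.0 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])))


def tmm_factors(
    matrix: SpotMatrix,
    annotation: AnnotationTable,
    library_sizes: dict,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_kept: int = 10,
) -> tuple[dict, dict]:
    """Per-column TMM factors (geometric mean 1 per channel) and references.

    Returns ``(factors, reference)`` where both are keyed by channel;
    ``reference[channel]`` is the gel_id of the reference column.
    Only cellular spots enter the M/A computation.
    """
    cellular = annotation.class_mask(matrix.spot_ids, SpotClass.cellular)
    factors: dict[str, np.ndarray] = {}
    reference: dict[str, str] = {}
    for ch in CHANNELS:
        sub = matrix.channel(ch)[cellular]
        lib = np.asarray(library_sizes[ch], dtype=float)
        if (lib <= 0).any():
            raise NormalizationError(f"nonpositive library size in {ch} channel")
        q75 = np.quantile(sub, 0.75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))  # lowest index on ties
        f = np.array(
            [
                _tmm_pair(sub[:, k], sub[:, ref_idx], lib[k], lib[ref_idx],
                          trim_m, trim_a, min_kept)
                for k in range(sub.shape[1])
            ]
        )
        f /= np.exp(np.mean(np.log(f)))
        factors[ch] = f
        reference[ch] = matrix.gel_ids[ref_idx]
    return factors, reference


def normalize_cpm_log2(
    matrix: SpotMatrix,
    library_sizes: dict,
    factors: dict,
    prior: float = 0.5,
) -> dict:
    """log2 volumes-per-million of effective library, per channel.

    ``value = log2(y / (N * f) * 1e6 + prior)``; the prior is a small
    offset on the per-million scale keeping zero-free data finite even
    for vanishing volumes.
    """
    if prior < 0:
        raise ValidationError("prior must be >= 0")
    out = {}
    for ch in CHANNELS:
        lib = np.asarray(library_sizes[ch], dtype=float)
        f = np.asarray(factors[ch], dtype=float)
        if (lib <= 0).any() or (f <= 0).any():
            raise NormalizationError(f"nonpositive library size or factor in {ch} channel")
        cpm = matrix.channel(ch) / (lib * f)[None, :] * 1e6
        values = np.log2(cpm + prior)
        if not np.isfinite(values).all():
            raise NormalizationError(f"non-finite normalized value in {ch} channel")
        out[ch] = values
    return out


@dataclass
class NormalizationResult:
    """Library sizes, TMM factors and the normalized log2 matrix."""

    spot_ids: list[str]
    gel_ids: list[str]
    library_sizes: dict  # channel -> (n_gels,)
    tmm_factors: dict  # channel -> (n_gels,), geometric mean 1 per channel
    reference: dict  # channel -> gel_id of TMM reference column
    normalized_log2: dict  # channel -> (n_spots, n_gels)
    params: dict = field(default_factory=dict)

    def factor_table(self) -> pd.DataFrame:
        rows = []
        for ch in CHANNELS:
            for j, gel in enumerate(self.gel_ids):
                rows.append(
                    {
                        "gel_id": gel,
                        "channel": ch,
                        "library_size": self.library_sizes[ch][j],
                        "tmm_factor": self.tmm_factors[ch][j],
                        "is_reference": gel == self.reference[ch],
                    }
                )
        return pd.DataFrame(rows)

    def normalized_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {"spot_id": self.spot_ids}
        for j, gel in enumerate(self.gel_ids):
            for ch in CHANNELS:
                cols[f"{gel}.{ch}"] = self.normalized_log2[ch][:, j]
        return pd.DataFrame(cols)


def normalize(
    matrix: SpotMatrix,
    annotation: AnnotationTable,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_kept: int = 10,
    prior: float = 0.5,
) -> NormalizationResult:
    """Full class-restricted normalization of a zero-free matrix."""
    lib = compute_library_sizes(matrix, annotation)
    factors, reference = tmm_factors(matrix, annotation, lib, trim_m, trim_a, min_kept)
    values = normalize_cpm_log2(matrix, lib, factors, prior)
    return NormalizationResult(
        spot_ids=list(matrix.spot_ids),
        gel_ids=list(matrix.gel_ids),
        library_sizes=lib,
        tmm_factors=factors,
        reference=reference,
        normalized_log2=values,
        params={"trim_m": trim_m, "trim_a": trim_a, "min_kept": min_kept, "prior": prior},
    )


def total_sum_normalize(matrix: SpotMatrix, prior: float = 0.5) -> NormalizationResult:
    """Standard-workflow comparator: totals over ALL spots, no TMM.

    Library sizes are full-column sums, all scaling factors are 1;
    the log2 CPM transform is identical to the main path so the two
    workflows differ only in the scaling they apply.
    """
    for ch in CHANNELS:
        if (matrix.channel(ch) <= 0).any():
            raise ValidationError(
                f"{ch} channel contains nonpositive values; run replace_zeros first"
            )
    lib = {ch: matrix.channel(ch).sum(axis=0) for ch in CHANNELS}
    ones = {ch: np.ones(matrix.n_gels) for ch in CHANNELS}
    values = normalize_cpm_log2(matrix, lib, ones, prior)
    return NormalizationResult(
        spot_ids=list(matrix.spot_ids),
        gel_ids=list(matrix.gel_ids),
        library_sizes=lib,
        tmm_factors=ones,
        reference={ch: matrix.gel_ids[0] for ch in CHANNELS},
        normalized_log2=values,
        params={"workflow": "standard_total_sum", "prior": prior},
    )
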