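"""Gene-set over-representation and activation scoring.

For each gene set the overlap with the significant molecules is tested
by a one-tailed Fisher exact test (upper-tail hypergeometric) against a
user-chosen background — by default the unique identified proteins of
the experiment, since over-representation among *detected* proteins is
the question being asked.  P-values are BH-corrected across sets.

When expected regulation directions are supplied, an activation
z-score compares observed fold-change signs with the predicted
pattern:

    z = (n_consistent - n_inconsistent) / sqrt(n_annotated)

so positive z predicts pathway activation, negative z inhibition, and
|z| <= sqrt(n_annotated).  Genes without an expected direction do not
enter the score; with no annotated gene the score is undefined and
reported as blank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSet, ValidationError
from .models import bh_adjust


@dataclass
class EnrichmentResult:
    """Per-set overlap statistics mirroring a canonical-pathway table."""

    set_id: str
    name: str
    n_overlap: int
    set_size: int  # |set ∩ background|
    ratio: float
    p: float
    p_bh: float
    z: Optional[float]
    molecules: list[str]  # overlapping genes, signed when direction known


def activation_zscore(
    observed_sign: Mapping[str, int], expected_direction: Mapping[str, str]
) -> Optional[float]:
    """Direction-match z-score over genes having both sign and prediction.

    ``observed_sign`` maps gene -> +1 (up) / -1 (down).  Returns None
    when no overlapping gene carries an expected direction.
    """
    n_cons = n_incons = 0
    for gene, direction in expected_direction.items():
        if gene not in observed_sign:
            continue
        sign = observed_sign[gene]
        if sign not in (-1, 1):
            raise ValidationError(f"observed sign for {gene!r} must be +1/-1, got {sign}")
        expected = 1 if direction == "up" else -1
        if sign == expected:
            n_cons += 1
        else:
            n_incons += 1
    n_annot = n_cons + n_incons
    if n_annot == 0:
        return None
    return (n_cons - n_incons) / np.sqrt(n_annot)


def fisher_enrichment(
    significant: Mapping[str, int] | Iterable[str],
    background: Iterable[str],
    genesets: Sequence[GeneSet],
) -> list[EnrichmentResult]:
    """One-tailed Fisher enrichment of ``significant`` genes in each set.

    ``significant`` may be a plain collection of genes or a mapping
    gene -> observed log2 sign (+1/-1); signs enable activation
    z-scores for sets with expected directions.  Sets are intersected
    with the background first; sets with an empty intersection are
    skipped with a warning.  ``ratio`` is overlap / |set ∩ background|.
    """
    background = set(background)
    if not background:
        raise ValidationError("background gene set is empty")
    if isinstance(significant, Mapping):
        signs = {g: s for g, s in significant.items()}
        sig = set(signs)
    else:
        signs = {}
        sig = set(significant)
    stray = sig - background
    if stray:
        raise ValidationError(
            f"significant genes outside the background: {sorted(stray)[:10]}"
        )
    m_total = len(background)
    n_sig = len(sig)
    results: list[EnrichmentResult] = []
    for gs in genesets:
        members = gs.members & background
        if not members:
            warnings.warn(f"gene set {gs.set_id!r} has no background overlap; skipped")
            continue
        overlap = sorted(members & sig)
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(population m_total, successes |set|, draws n_sig)
        p = float(hypergeom.sf(k - 1, m_total, len(members), n_sig))
        observed = {g: signs[g] for g in overlap if g in signs}
        z = activation_zscore(observed, gs.expected_direction)
        molecules = [
            f"{g}{'+' if signs[g] > 0 else '-'}" if g in signs else g for g in overlap
        ]
        results.append(
            EnrichmentResult(
                set_id=gs.set_id,
                name=gs.name,
                n_overlap=k,
                set_size=len(members),
                ratio=k / len(members),
                p=min(p, 1.0),
                p_bh=np.nan,
                z=z,
                molecules=molecules,
            )
        )
    if results:
        q = bh_adjust([r.p for r in results])
        for r, qv in zip(results, q):
            r.p_bh = float(qv)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view with the canonical p_bh / ratio / z / molecules columns."""
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "name": [r.name for r in results],
            "n_overlap": [r.n_overlap for r in results],
            "set_size": [r.set_size for r in results],
            "ratio": [r.ratio for r in results],
            "p": [r.p for r in results],
            "p_bh": [r.p_bh for r in results],
            "z": [r.z if r.z is not None else np.nan for r in results],
            "molecules": [",".join(r.molecules) for r in results],
        }
    )
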