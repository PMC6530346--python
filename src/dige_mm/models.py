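"""Per-spot mixed models with internal-standard random intercepts.

For each spot ``s`` the normalized log2 volumes of the two channels of
gel ``g`` are modeled as

    y_{g,c} = alpha_{group(g)} + delta * 1[c=sample]
              + sum_e beta_e x_e(g) 1[c=sample] + b_g + eps_{g,c},

with a gel-level random intercept ``b_g ~ N(0, sigma2_gel)`` carrying
everything the two channels of a gel share (loading, labeling, scan
gain — the role of the internal pooled standard) and independent
channel noise ``eps ~ N(0, sigma2_resid)``.  The four treatment
coefficients are

* ``fluid_SCB``   — chronic SCB-fluid exposure (active for SCB, SCB_AG),
* ``fluid_DCB``   — chronic DCB-fluid exposure (active for DCB, DCB_AG),
* ``additive_SCB_AG`` / ``additive_DCB_AG`` — the incremental
  alanyl-glutamine effect within each fluid arm,

all expressed on the sample channel relative to control, so
``2**estimate`` is the fold-change attributable to that effect.

Because every gel contributes exactly one sample and one IPS
observation, the REML problem is balanced and splits into two
orthogonal strata: per-gel differences ``d_g = y_sample - y_ips``
(free of ``b_g``) and per-gel means.  The group main effects absorb
the entire between-gel projection of the treatment covariates, so the
REML estimates of the betas — and their standard errors — equal those
of an ordinary least-squares fit of ``d_g`` on the treatment design
*exactly*, which is the precise sense in which the mixed model is
equivalent to subtracting the internal standard from the sample.  The
fit here uses that closed form (vectorized across spots); tests verify
equality with a generic REML mixed-model fitter.  The between stratum
yields the variance components and shrunken (BLUP) gel intercepts used
for visualization.

Wald t statistics use the within-stratum residual degrees of freedom
(n_gels - 5), the df under which the difference-OLS equivalence makes
the t distribution exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    AnnotationTable,
    DesignTable,
    Group,
    SpotMatrix,
    ValidationError,
)
from .preprocess import ZeroPolicy, replace_zeros
from .tmm import NormalizationResult, total_sum_normalize

COEFFICIENTS = ("fluid_SCB", "fluid_DCB", "additive_SCB_AG", "additive_DCB_AG")

#: groups in which each coefficient's covariate is active (sample channel)
_ACTIVE = {
    "fluid_SCB": (Group.SCB, Group.SCB_AG),
    "fluid_DCB": (Group.DCB, Group.DCB_AG),
    "additive_SCB_AG": (Group.SCB_AG,),
    "additive_DCB_AG": (Group.DCB_AG,),
}

#: two-group contrast each coefficient estimates (treated, reference)
_PAIRWISE = {
    "fluid_SCB": (Group.SCB, Group.control),
    "fluid_DCB": (Group.DCB, Group.control),
    "additive_SCB_AG": (Group.SCB_AG, Group.SCB),
    "additive_DCB_AG": (Group.DCB_AG, Group.DCB),
}


def design_matrix(design: DesignTable, gel_ids: list[str]) -> np.ndarray:
    """Treatment design (n_gels x 4) in ``COEFFICIENTS`` order.

    Raises if any of the five groups is empty (singular design).
    """
    sizes = design.group_sizes()
    for g in Group:
        if sizes[g] == 0:
            raise ValidationError(f"design is singular: group {g.name} has no gels")
    x = np.zeros((len(gel_ids), len(COEFFICIENTS)))
    for i, gel in enumerate(gel_ids):
        grp = design.group_of(gel)
        for k, coef in enumerate(COEFFICIENTS):
            if grp in _ACTIVE[coef]:
                x[i, k] = 1.0
    return x


def _group_indicators(design: DesignTable, gel_ids: list[str]) -> np.ndarray:
    g_index = {g: k for k, g in enumerate(Group)}
    z = np.zeros((len(gel_ids), len(Group)))
    for i, gel in enumerate(gel_ids):
        z[i, g_index[design.group_of(gel)]] = 1.0
    return z


@dataclass
class SpotModelResults:
    """Per-spot x per-coefficient inference plus variance components."""

    table: pd.DataFrame  # spot_id, coefficient, estimate, se, t, df, p, q, fold_change
    variance_components: pd.DataFrame  # spot_id, sigma2_gel, sigma2_resid, converged
    random_intercepts: np.ndarray  # (n_spots, n_gels) BLUP b_hat
    spot_ids: list[str]
    gel_ids: list[str]
    method: str

    def coefficient_frame(self, coefficient: str) -> pd.DataFrame:
        if coefficient not in COEFFICIENTS:
            raise ValidationError(
                f"unknown coefficient {coefficient!r}; expected one of {COEFFICIENTS}"
            )
        sub = self.table[self.table["coefficient"] == coefficient]
        return sub.set_index("spot_id")

    def significant_spots(
        self, coefficient: str, alpha: float = 0.05, measure: str = "p"
    ) -> list[str]:
        if measure not in ("p", "q"):
            raise ValidationError(f"measure must be 'p' or 'q', got {measure!r}")
        sub = self.coefficient_frame(coefficient)
        ok = self.variance_components.set_index("spot_id")["converged"]
        sub = sub[ok.reindex(sub.index).fillna(False).astype(bool)]
        return sub.index[sub[measure] < alpha].tolist()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (stable under input order)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if (~np.isfinite(p)).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _inference_frame(
    spot_ids, est, se, df, converged
) -> tuple[pd.DataFrame, np.ndarray]:
    """Long-format t/p/q table from per-spot estimates (spots x 4)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    rows = []
    for k, coef in enumerate(COEFFICIENTS):
        pk = p[:, k]
        qk = np.full_like(pk, np.nan)
        if converged.any():
            qk[converged] = bh_adjust(pk[converged])
        for i, spot in enumerate(spot_ids):
            rows.append(
                (
                    spot,
                    coef,
                    est[i, k],
                    se[i, k],
                    t[i, k],
                    float(df),
                    pk[i],
                    qk[i],
                    2.0 ** est[i, k],
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "spot_id",
            "coefficient",
            "estimate",
            "se",
            "t",
            "df",
            "p",
            "q",
            "fold_change",
        ],
    )
    return table, p


def fit_spot_models(
    normalized: NormalizationResult,
    design: DesignTable,
    tests: str = "wald",
) -> SpotModelResults:
    """Fit the mixed model to every spot of a normalized matrix.

    ``tests="wald"`` (default) reports Wald t statistics on the model
    coefficients; ``tests="pairwise"`` instead runs two-sample t-tests
    of the per-gel differences between the two groups each coefficient
    contrasts (the post-hoc reading of "t-tests").  Estimates are the
    same group-mean contrasts in both modes.
    """
    if tests not in ("wald", "pairwise"):
        raise ValidationError(f"tests must be 'wald' or 'pairwise', got {tests!r}")
    gel_ids = normalized.gel_ids
    spot_ids = normalized.spot_ids
    sizes = {g: len(design.gels_in(g)) for g in Group}
    if sizes[Group.control] == 0:
        raise ValidationError("model fitting requires at least one control gel")
    x = design_matrix(design, gel_ids)
    n_gels = len(gel_ids)

    sample = normalized.normalized_log2["sample"]
    ips = normalized.normalized_log2["ips"]
    d = sample - ips  # within-gel stratum, free of b_g
    mean = (sample + ips) / 2.0  # between-gel stratum

    # within stratum: OLS of d on [1 | X]  (exact REML betas and SEs)
    xd = np.column_stack([np.ones(n_gels), x])
    p_fixed = xd.shape[1]
    df_within = n_gels - p_fixed
    if df_within <= 0:
        raise ValidationError("no residual degrees of freedom (too few gels)")
    xtx_inv = np.linalg.inv(xd.T @ xd)
    proj = xtx_inv @ xd.T
    coefs = d @ proj.T  # (spots, 5)
    resid = d - coefs @ xd.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2_d = rss / df_within  # Var(d) = 2 * sigma2_resid
    converged = np.isfinite(sigma2_d) & (sigma2_d > 0)
    if not converged.all():
        warnings.warn(
            f"{int((~converged).sum())} spot(s) with degenerate (zero) residual "
            "variance flagged and excluded from significance counts"
        )
    se = np.sqrt(np.outer(sigma2_d, np.diag(xtx_inv)))

    # between stratum: group means of per-gel means -> variance components
    z = _group_indicators(design, gel_ids)
    proj_z = np.linalg.inv(z.T @ z) @ z.T
    fitted_m = (mean @ proj_z.T) @ z.T
    resid_m = mean - fitted_m
    rss_m = np.einsum("ij,ij->i", resid_m, resid_m)
    df_between = n_gels - z.shape[1]
    sigma2_resid = sigma2_d / 2.0
    v_between = rss_m / df_between  # estimates sigma2_gel + sigma2_resid/2
    sigma2_gel = np.maximum(v_between - sigma2_resid / 2.0, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(
            sigma2_gel + sigma2_resid / 2.0 > 0,
            sigma2_gel / (sigma2_gel + sigma2_resid / 2.0),
            0.0,
        )
    blup = shrink[:, None] * resid_m

    if tests == "wald":
        est4, se4, df_t = coefs[:, 1:], se[:, 1:], df_within
        table, _ = _inference_frame(spot_ids, est4, se4, df_t, converged)
    else:
        table = _pairwise_table(d, spot_ids, design, gel_ids, converged)

    vc = pd.DataFrame(
        {
            "spot_id": spot_ids,
            "sigma2_gel": sigma2_gel,
            "sigma2_resid": sigma2_resid,
            "converged": converged,
        }
    )
    return SpotModelResults(
        table=table,
        variance_components=vc,
        random_intercepts=blup,
        spot_ids=list(spot_ids),
        gel_ids=list(gel_ids),
        method=f"mixed_reml_{tests}",
    )


def _pairwise_table(
    d: np.ndarray,
    spot_ids,
    design: DesignTable,
    gel_ids: list[str],
    converged: np.ndarray,
) -> pd.DataFrame:
    gel_pos = {g: i for i, g in enumerate(gel_ids)}
    est = np.empty((d.shape[0], 4))
    se = np.empty_like(est)
    dfs = np.empty(4)
    for k, coef in enumerate(COEFFICIENTS):
        treated, ref = _PAIRWISE[coef]
        it = [gel_pos[g] for g in design.gels_in(treated)]
        ir = [gel_pos[g] for g in design.gels_in(ref)]
        if len(it) < 2 or len(ir) < 2:
            raise ValidationError(
                f"coefficient {coef}: groups {treated.name}/{ref.name} need >=2 gels "
                "each for a two-sample t-test"
            )
        a, b = d[:, it], d[:, ir]
        n1, n0 = a.shape[1], b.shape[1]
        est[:, k] = a.mean(axis=1) - b.mean(axis=1)
        sp2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n0 - 1)) / (
            n1 + n0 - 2
        )
        se[:, k] = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        dfs[k] = n1 + n0 - 2
    # per-coefficient dfs are equal only in balanced designs; report each
    tables = []
    for k, coef in enumerate(COEFFICIENTS):
        tab, _ = _inference_frame(
            spot_ids, est[:, [k]].repeat(4, axis=1), se[:, [k]].repeat(4, axis=1),
            dfs[k], converged
        )
        tables.append(tab[tab["coefficient"] == coef])
    return pd.concat(tables, ignore_index=True)


def visualize_adjust(
    normalized: NormalizationResult, results: SpotModelResults
) -> dict:
    """Subtract fitted (BLUP) gel intercepts from the normalized values.

    Between-gel level differences shared by the two channels are
    removed for display; within-gel contrasts — hence every
    coefficient estimate — are unchanged.
    """
    return {
        ch: normalized.normalized_log2[ch] - results.random_intercepts
        for ch in normalized.normalized_log2
    }


def count_significant(
    results: SpotModelResults,
    annotation: AnnotationTable,
    alpha: float = 0.05,
    measure: str = "p",
    coefficients=None,
) -> dict:
    """Spot counts, unique-accession counts and pairwise overlaps.

    ``measure`` selects raw p-values (``"p"``) or BH q-values
    (``"q"``).  Unique-ID counts consider only spots with an accession;
    several spots of one protein count once.
    """
    coefficients = list(coefficients) if coefficients is not None else list(COEFFICIENTS)
    for coef in coefficients:
        if coef not in COEFFICIENTS:
            raise ValidationError(
                f"unknown coefficient {coef!r}; expected one of {COEFFICIENTS}"
            )
    sig: dict[str, set] = {
        coef: set(results.significant_spots(coef, alpha, measure)) for coef in coefficients
    }
    per_coef = {}
    for coef in coefficients:
        accessions = {
            acc
            for s in sig[coef]
            if (acc := annotation.accession_of(s)) is not None
        }
        per_coef[coef] = {"n_spots": len(sig[coef]), "n_unique_ids": len(accessions)}
    overlap = {}
    for i, c1 in enumerate(coefficients):
        for c2 in coefficients[i + 1 :]:
            both = sig[c1] & sig[c2]
            accs = {
                acc for s in both if (acc := annotation.accession_of(s)) is not None
            }
            overlap[f"{c1}&{c2}"] = {"n_spots": len(both), "n_unique_ids": len(accs)}
    return {
        "measure": measure,
        "alpha": alpha,
        "per_coefficient": per_coef,
        "overlap": overlap,
    }


def significant_molecules(
    results: SpotModelResults,
    annotation: AnnotationTable,
    coefficient: str,
    alpha: float = 0.05,
    measure: str = "p",
) -> dict:
    """Gene -> observed log2 direction (+1/-1) among significant spots.

    Spot-level estimates are averaged per gene before taking the sign,
    condensing spot information to the molecule level.
    """
    sub = results.coefficient_frame(coefficient)
    spots = results.significant_spots(coefficient, alpha, measure)
    per_gene: dict[str, list[float]] = {}
    for s in spots:
        gene = annotation.gene_of(s)
        if gene is not None:
            per_gene.setdefault(gene, []).append(float(sub.loc[s, "estimate"]))
    return {
        g: (1 if float(np.mean(v)) >= 0 else -1) for g, v in per_gene.items() if v
    }


def standard_workflow(
    matrix: SpotMatrix,
    design: DesignTable,
    policy: ZeroPolicy = ZeroPolicy(),
    prior: float = 0.5,
) -> SpotModelResults:
    """Classic 2D-DiGE processing used as the comparison arm.

    Each column is scaled by its total volume over *all* spots, log2
    transformed, the internal standard is subtracted from the sample
    per gel, and each coefficient is tested by a two-sample t-test of
    treated vs reference per-gel differences.  The output schema is
    identical to the main pipeline for side-by-side comparison.
    """
    positive = replace_zeros(matrix, policy)
    norm = total_sum_normalize(positive, prior=prior)
    d = norm.normalized_log2["sample"] - norm.normalized_log2["ips"]
    converged = np.ones(len(norm.spot_ids), dtype=bool)
    table = _pairwise_table(d, norm.spot_ids, design, norm.gel_ids, converged)
    vc = pd.DataFrame(
        {
            "spot_id": norm.spot_ids,
            "sigma2_gel": np.nan,
            "sigma2_resid": np.nan,
            "converged": converged,
        }
    )
    return SpotModelResults(
        table=table,
        variance_components=vc,
        random_intercepts=np.zeros((len(norm.spot_ids), len(norm.gel_ids))),
        spot_ids=list(norm.spot_ids),
        gel_ids=list(norm.gel_ids),
        method="standard_total_sum_ttest",
    )
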