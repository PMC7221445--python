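"""Genetically predicted expression from eQTL weight sets.

A gene's predicted expression for sample *i* is the weighted dosage sum
``x_i = sum_j w_j * d_ij`` over the gene's eQTLs, after harmonizing the
allele orientation of the weight table to the dosage file.  Predicted
expression is deliberately left unstandardized: both interaction score
tests are invariant to a rescaling of x.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .types import GenotypeMatrix, PredictedExpression, WeightSet

logger = logging.getLogger("gxescan.expression")

__all__ = [
    "harmonize_alleles",
    "predict_expression",
    "filter_genes_by_heritability",
    "UnpredictableGeneError",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class UnpredictableGeneError(ValueError):
    """No eQTL of the gene could be matched to the genotype data."""


def _strand_flip(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele.upper())


def _is_ambiguous(a: str, b: str) -> bool:
    """A/T and C/G pairs cannot be oriented across strands."""
    return _strand_flip(a.upper()) == b.upper()


def harmonize_alleles(
    ws: WeightSet,
    g: GenotypeMatrix,
    drop_ambiguous: bool = True,
) -> WeightSet:
    """Orient a weight set to a genotype matrix's allele coding.

    For each eQTL present in ``g``: matching alleles keep the weight;
    swapped effect/other alleles negate the weight and mark the dosage for
    complementing (``d -> 2 - d``); a match after strand complement is
    treated like the corresponding direct case unless the SNP is
    strand-ambiguous (A/T or C/G), which is dropped when ``drop_ambiguous``.
    eQTLs absent from ``g`` or with irreconcilable alleles are dropped and
    counted in ``n_dropped``.
    """
    index = g.variant_index()
    gv = g.variants
    keep_ids, keep_ea, keep_oa, keep_w, keep_cmpl = [], [], [], [], []
    n_dropped = 0
    for vid, ea, oa, w, cmpl in zip(
        ws.variant_ids, ws.effect_alleles, ws.other_alleles,
        ws.weights, ws.dosage_complement,
    ):
        j = index.get(vid)
        if j is None:
            n_dropped += 1
            continue
        g_ea = str(gv.at[j, "effect_allele"]).upper()
        g_oa = str(gv.at[j, "other_allele"]).upper()
        ea_u, oa_u = ea.upper(), oa.upper()
        ambiguous = _is_ambiguous(ea_u, oa_u)
        if (ea_u, oa_u) == (g_ea, g_oa):
            new_w, new_cmpl = w, cmpl
        elif (ea_u, oa_u) == (g_oa, g_ea):
            if ambiguous and drop_ambiguous:
                # indistinguishable from a strand flip: orientation unknowable
                n_dropped += 1
                continue
            new_w, new_cmpl = -w, not cmpl
        elif (_strand_flip(ea_u), _strand_flip(oa_u)) == (g_ea, g_oa):
            if ambiguous and drop_ambiguous:
                n_dropped += 1
                continue
            new_w, new_cmpl = w, cmpl
        elif (_strand_flip(ea_u), _strand_flip(oa_u)) == (g_oa, g_ea):
            if ambiguous and drop_ambiguous:
                n_dropped += 1
                continue
            new_w, new_cmpl = -w, not cmpl
        else:
            n_dropped += 1
            continue
        keep_ids.append(vid)
        keep_ea.append(g_ea)
        keep_oa.append(g_oa)
        keep_w.append(new_w)
        keep_cmpl.append(new_cmpl)
    if not keep_ids:
        raise UnpredictableGeneError(
            f"gene {ws.gene_id}: no eQTL could be harmonized to the genotype data"
        )
    if n_dropped:
        logger.info("gene %s: dropped %d of %d eQTLs during harmonization",
                    ws.gene_id, n_dropped, ws.n_snps)
    return replace(
        ws,
        variant_ids=keep_ids,
        effect_alleles=keep_ea,
        other_alleles=keep_oa,
        weights=np.asarray(keep_w, dtype=float),
        dosage_complement=np.asarray(keep_cmpl, dtype=bool),
        n_dropped=ws.n_dropped + n_dropped,
    )


def predict_expression(ws: WeightSet, g: GenotypeMatrix) -> PredictedExpression:
    """Compute predicted expression ``x = D @ w`` for a harmonized weight set.

    ``ws`` must already be oriented to ``g`` (see :func:`harmonize_alleles`);
    variants still absent from ``g`` contribute zero and are counted as
    dropped.  Raises :class:`UnpredictableGeneError` when no eQTL remains.
    """
    index = g.variant_index()
    cols, weights, complement = [], [], []
    n_missing = 0
    for vid, w, cmpl in zip(ws.variant_ids, ws.weights, ws.dosage_complement):
        j = index.get(vid)
        if j is None:
            n_missing += 1
            continue
        cols.append(j)
        weights.append(w)
        complement.append(cmpl)
    if not cols:
        raise UnpredictableGeneError(f"gene {ws.gene_id}: zero usable eQTLs")
    d = g.dosages[:, cols]
    complement = np.asarray(complement, dtype=bool)
    if complement.any():
        d = np.where(complement[None, :], 2.0 - d, d)
    values = d @ np.asarray(weights, dtype=float)
    return PredictedExpression(
        gene_id=ws.gene_id,
        values=values,
        n_snps_used=len(cols),
        n_snps_dropped=ws.n_dropped + n_missing,
    )


def filter_genes_by_heritability(
    weight_sets: list[WeightSet], r2_min: float = 0.01
) -> list[WeightSet]:
    """Keep genes whose predictive R^2 meets the heritability floor (>=)."""
    kept = [ws for ws in weight_sets if ws.predictive_r2 >= r2_min]
    logger.info("heritability filter kept %d of %d genes (R2 >= %g)",
                len(kept), len(weight_sets), r2_min)
    return kept
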