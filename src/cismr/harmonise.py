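"""Allele harmonisation of exposure and outcome summary statistics.

Two-sample MR needs both datasets expressed for the *same* effect allele.
Depending on how each study reported the variant, the outcome record may be
aligned, allele-swapped (flip the sign of beta and eaf -> 1-eaf), or reported
on the opposite strand (recode via A<->T, C<->G, then re-test).  Palindromic
variants (A/T or C/G) cannot be strand-resolved from allele labels alone and
are adjudicated by allele frequency: they are retained only when both
frequencies fall on the same side of 0.5 and both minor-allele frequencies
are below ``palindromic_maf_limit`` (default 0.42); otherwise they are
dropped as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .sumstats import RegionData, TraitMeta, VariantAssoc

__all__ = [
    "HarmonisedPair",
    "InstrumentSet",
    "harmonise_pair",
    "build_instrument_set",
    "harmonise_regions",
    "write_harmonisation_report",
    "PALINDROMIC_MAF_LIMIT",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_MAF_LIMIT = 0.42

RETAINED = ("aligned", "flipped", "strand_corrected")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return COMPLEMENT[effect_allele] == other_allele


@dataclass(frozen=True)
class HarmonisedPair:
    """Exposure and outcome effects for one variant on a shared effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float]
    eaf_out: Optional[float]
    status: str
    effect_allele: str = ""
    other_allele: str = ""

    @property
    def retained(self) -> bool:
        return self.status in RETAINED

    @property
    def ratio(self) -> float:
        return self.beta_out / self.beta_exp


@dataclass
class InstrumentSet:
    """Harmonised exposure-outcome pairs for one protein-outcome analysis."""

    exposure: TraitMeta
    outcome: TraitMeta
    pairs: list  # retained HarmonisedPair only
    log: dict = field(default_factory=dict)
    report: list = field(default_factory=list)  # every attempted pair

    def __post_init__(self):
        ids = [p.variant_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in instrument set")
        if any(not p.retained for p in self.pairs):
            raise ValueError("instrument set may only contain retained pairs")

    def __len__(self):
        return len(self.pairs)


def harmonise_pair(
    exp: VariantAssoc,
    out: VariantAssoc,
    palindromic_maf_limit: float = PALINDROMIC_MAF_LIMIT,
) -> HarmonisedPair:
    """Harmonise one exposure/outcome record pair onto the exposure's effect allele."""
    if exp.variant_id != out.variant_id:
        raise ValueError(f"variant id mismatch: {exp.variant_id} vs {out.variant_id}")

    def build(beta_out, eaf_out, status):
        return HarmonisedPair(
            variant_id=exp.variant_id,
            beta_exp=exp.beta,
            se_exp=exp.se,
            beta_out=beta_out,
            se_out=out.se,
            eaf_exp=exp.eaf,
            eaf_out=eaf_out,
            status=status,
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
        )

    ea, oa = exp.effect_allele, exp.other_allele
    if is_palindromic(ea, oa):
        # strand flip of a palindromic pair is indistinguishable from an
        # allele swap; labels only tell us whether the pair matches at all
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            return build(out.beta, out.eaf, "dropped_mismatch")
        swapped = out.effect_allele != ea
        beta_o = -out.beta if swapped else out.beta
        eaf_o = None if out.eaf is None else (1.0 - out.eaf if swapped else out.eaf)
        if exp.eaf is None or eaf_o is None:
            return build(beta_o, eaf_o, "dropped_palindromic")
        same_side = (exp.eaf - 0.5) * (eaf_o - 0.5) > 0
        inferable = (
            min(exp.eaf, 1 - exp.eaf) < palindromic_maf_limit
            and min(eaf_o, 1 - eaf_o) < palindromic_maf_limit
        )
        if same_side and inferable:
            return build(beta_o, eaf_o, "flipped" if swapped else "aligned")
        return build(beta_o, eaf_o, "dropped_palindromic")

    if (out.effect_allele, out.other_allele) == (ea, oa):
        return build(out.beta, out.eaf, "aligned")
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return build(-out.beta, None if out.eaf is None else 1.0 - out.eaf, "flipped")
    cea, coa = COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele]
    if (cea, coa) == (ea, oa):
        return build(out.beta, out.eaf, "strand_corrected")
    if (cea, coa) == (oa, ea):
        return build(-out.beta, None if out.eaf is None else 1.0 - out.eaf, "strand_corrected")
    return build(out.beta, out.eaf, "dropped_mismatch")


def build_instrument_set(
    instruments: list,
    outcome_region: RegionData,
    exposure_meta: Optional[TraitMeta] = None,
    palindromic_maf_limit: float = PALINDROMIC_MAF_LIMIT,
) -> InstrumentSet:
    """Intersect clumped exposure instruments with the outcome and harmonise.

    Instruments absent from the outcome are logged as ``absent``; harmonisation
    failures are logged by status.  Raises when no pair is retained.
    """
    out_by_id = outcome_region.by_id()
    retained, report = [], []
    log = {"absent": 0}
    for v in instruments:
        o = out_by_id.get(v.variant_id)
        if o is None:
            log["absent"] += 1
            continue
        pair = harmonise_pair(v, o, palindromic_maf_limit)
        report.append(pair)
        log[pair.status] = log.get(pair.status, 0) + 1
        if pair.retained:
            retained.append(pair)
    if not retained:
        raise ValueError(
            f"no instruments retained after harmonisation (log: {log})"
        )
    meta = exposure_meta or TraitMeta(trait_id="exposure")
    return InstrumentSet(meta, outcome_region.trait, retained, log, report)


def harmonise_regions(
    exposure_region: RegionData,
    outcome_region: RegionData,
    palindromic_maf_limit: float = PALINDROMIC_MAF_LIMIT,
) -> tuple:
    """Align two full regions to their shared, harmonisable variants.

    Used for colocalization, which needs every variant in the locus (not just
    instruments) expressed for a common effect allele and in a common order.
    Returns (exposure RegionData, outcome RegionData) over the retained
    intersection; the exposure's LD matrix, when present, is subset to match.
    """
    out_by_id = outcome_region.by_id()
    kept_exp, kept_out = [], []
    for v in exposure_region.variants:
        o = out_by_id.get(v.variant_id)
        if o is None:
            continue
        pair = harmonise_pair(v, o, palindromic_maf_limit)
        if not pair.retained:
            continue
        kept_exp.append(v)
        kept_out.append(
            VariantAssoc(
                variant_id=v.variant_id,
                chrom=o.chrom,
                pos=o.pos,
                effect_allele=v.effect_allele,
                other_allele=v.other_allele,
                beta=pair.beta_out,
                se=pair.se_out,
                eaf=pair.eaf_out,
                n=o.n,
            )
        )
    if not kept_exp:
        raise ValueError("no shared harmonisable variants between regions")
    exp_sub = exposure_region.with_variants(kept_exp)
    out_sub = RegionData(outcome_region.trait, kept_out)
    return exp_sub, out_sub


def write_harmonisation_report(pairs: list, path) -> None:
    """One row per attempted variant with status and transformed effects."""
    df = pd.DataFrame(
        [
            {
                "variant_id": p.variant_id,
                "effect_allele": p.effect_allele,
                "other_allele": p.other_allele,
                "beta_exp": p.beta_exp,
                "se_exp": p.se_exp,
                "beta_out": p.beta_out,
                "se_out": p.se_out,
                "eaf_exp": p.eaf_exp,
                "eaf_out": p.eaf_out,
                "status": p.status,
            }
            for p in pairs
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
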