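"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs each SNP's exposure and outcome effects expressed for
the *same* effect allele.  Files from different GWAS may report the other
allele (beta sign must flip), the other strand (alleles must be
complemented), or both.  Palindromic SNPs (A/T, C/G) cannot be oriented
from allele labels alone: they are resolved by effect-allele frequency when
both frequencies are available and clearly away from 0.5, and dropped
otherwise — the conservative convention in two-sample MR practice.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ACTION_KEPT, ACTION_SIGN_FLIPPED, ACTION_STRAND_COMPLEMENTED, COMPLEMENT,
    DROP_MISMATCH, DROP_MISSING, DROP_PALINDROMIC, HarmonizedSet, InputError,
    SummaryStats, VALID_ALLELES,
)

DEFAULT_AF_WINDOW = (0.42, 0.58)


def is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def _intermediate(eaf: float | None, window) -> bool:
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        return True  # unknown frequency cannot orient a palindrome
    return window[0] <= eaf <= window[1]


def _align_record(ref_ea: str, ref_oa: str, ref_eaf,
                  ea: str, oa: str, beta: float, eaf,
                  af_window) -> tuple[str, float, float | None]:
    """Align one source record to the reference allele orientation.

    Returns ``(action, aligned_beta, aligned_eaf)``; the action is a drop
    label when alignment is impossible.
    """
    if not ({ea, oa} <= VALID_ALLELES and {ref_ea, ref_oa} <= VALID_ALLELES):
        return DROP_MISMATCH, beta, eaf
    eaf = None if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)) else float(eaf)
    ref_eaf = (None if ref_eaf is None
               or (isinstance(ref_eaf, float) and np.isnan(ref_eaf)) else float(ref_eaf))

    if is_palindromic(ref_ea, ref_oa):
        if {ea, oa} != {ref_ea, ref_oa}:
            return DROP_MISMATCH, beta, eaf
        # textual alignment first: complementing a palindromic SNP swaps
        # its effect/other labels, so strand cannot be read from alleles
        if ea == ref_ea:
            action, b, q = ACTION_KEPT, beta, eaf
        else:
            action, b, q = ACTION_SIGN_FLIPPED, -beta, (None if eaf is None else 1 - eaf)
        if _intermediate(ref_eaf, af_window) or _intermediate(q, af_window):
            return DROP_PALINDROMIC, b, q
        if (ref_eaf < 0.5) == (q < 0.5):
            return action, b, q
        # discordant frequencies: the source reported the other strand
        return ACTION_STRAND_COMPLEMENTED, -b, 1 - q

    # non-palindromic: allele labels fully determine orientation
    if (ea, oa) == (ref_ea, ref_oa):
        return ACTION_KEPT, beta, eaf
    if (ea, oa) == (ref_oa, ref_ea):
        return ACTION_SIGN_FLIPPED, -beta, (None if eaf is None else 1 - eaf)
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return ACTION_STRAND_COMPLEMENTED, beta, eaf
    if (cea, coa) == (ref_oa, ref_ea):
        return ACTION_STRAND_COMPLEMENTED, -beta, (None if eaf is None else 1 - eaf)
    return DROP_MISMATCH, beta, eaf


def harmonize_pair(exposure: SummaryStats, outcome: SummaryStats,
                   af_window: tuple[float, float] = DEFAULT_AF_WINDOW
                   ) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles, SNP by SNP.

    Every exposure SNP receives exactly one action: ``kept``,
    ``sign_flipped`` or ``strand_complemented`` when retained, or a
    ``dropped:*`` reason.  SNPs absent from the outcome file are
    ``dropped:missing_in_source``.
    """
    exp_tab = exposure.table.set_index("rsid", drop=False)
    out_tab = outcome.table.set_index("rsid", drop=False)
    shared = [r for r in exposure.rsids if r in out_tab.index]
    if not shared:
        raise InputError(
            f"no shared rsids between {exposure.trait_name!r} and "
            f"{outcome.trait_name!r}")

    actions: dict[str, str] = {}
    rows = []
    for rsid in exposure.rsids:
        if rsid not in out_tab.index:
            actions[rsid] = DROP_MISSING
            continue
        e, o = exp_tab.loc[rsid], out_tab.loc[rsid]
        action, by, oeaf = _align_record(
            e["effect_allele"], e["other_allele"], e["eaf"],
            o["effect_allele"], o["other_allele"], float(o["beta"]), o["eaf"],
            af_window)
        actions[rsid] = action
        if action.startswith("dropped"):
            continue
        rows.append((rsid, float(e["beta"]), float(e["se"]),
                     float(by), float(o["se"]),
                     np.nan if pd.isna(e["eaf"]) else float(e["eaf"]),
                     np.nan if pd.isna(e["n"]) else float(e["n"]),
                     np.nan if pd.isna(o["n"]) else float(o["n"])))

    if rows:
        rsids, bx, bxse, by, byse, eaf, nx, ny = map(list, zip(*rows))
    else:
        rsids, bx, bxse, by, byse, eaf, nx, ny = [], [], [], [], [], [], [], []
    return HarmonizedSet(
        rsids=list(rsids),
        exposure_names=[exposure.trait_name],
        exposure_beta=np.asarray(bx, float).reshape(-1, 1),
        exposure_se=np.asarray(bxse, float).reshape(-1, 1),
        outcome_beta=np.asarray(by, float),
        outcome_se=np.asarray(byse, float),
        actions=actions,
        eaf=np.asarray(eaf, float),
        exposure_n=np.asarray(nx, float).reshape(-1, 1),
        outcome_n=np.asarray(ny, float),
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
    )


def harmonize_multi(exposures: Sequence[SummaryStats], outcome: SummaryStats,
                    af_window: tuple[float, float] = DEFAULT_AF_WINDOW,
                    instruments: Iterable[str] | None = None) -> HarmonizedSet:
    """Harmonize several exposures and one outcome to a shared orientation.

    ``instruments`` names the union instrument panel (typically: SNPs
    genome-wide significant in at least one exposure, after clumping); by
    default the union of all exposure rsids is used.  A union SNP must be
    present in *every* exposure file and the outcome file, else it is
    ``dropped:missing_in_source`` — absences are not zero-filled, since
    that would fabricate null associations.  Orientation follows the first
    exposure's alleles.
    """
    if len(exposures) < 2:
        raise InputError("harmonize_multi needs >= 2 exposures")
    tabs = [e.table.set_index("rsid", drop=False) for e in exposures]
    out_tab = outcome.table.set_index("rsid", drop=False)
    if instruments is None:
        union: list[str] = []
        seen = set()
        for e in exposures:
            for r in e.rsids:
                if r not in seen:
                    union.append(r)
                    seen.add(r)
    else:
        union = list(instruments)

    p = len(exposures)
    actions: dict[str, str] = {}
    rows = []
    for rsid in union:
        if any(rsid not in t.index for t in tabs) or rsid not in out_tab.index:
            actions[rsid] = DROP_MISSING
            continue
        ref = tabs[0].loc[rsid]
        ref_ea, ref_oa, ref_eaf = ref["effect_allele"], ref["other_allele"], ref["eaf"]
        betas = [float(ref["beta"])]
        ses = [float(ref["se"])]
        ns = [np.nan if pd.isna(ref["n"]) else float(ref["n"])]
        action = ACTION_KEPT
        ok = True
        for t in tabs[1:]:
            r = t.loc[rsid]
            act, b, _ = _align_record(ref_ea, ref_oa, ref_eaf,
                                      r["effect_allele"], r["other_allele"],
                                      float(r["beta"]), r["eaf"], af_window)
            if act.startswith("dropped"):
                actions[rsid] = act
                ok = False
                break
            action = _worst_action(action, act)
            betas.append(b)
            ses.append(float(r["se"]))
            ns.append(np.nan if pd.isna(r["n"]) else float(r["n"]))
        if not ok:
            continue
        o = out_tab.loc[rsid]
        act, by, _ = _align_record(ref_ea, ref_oa, ref_eaf,
                                   o["effect_allele"], o["other_allele"],
                                   float(o["beta"]), o["eaf"], af_window)
        if act.startswith("dropped"):
            actions[rsid] = act
            continue
        actions[rsid] = _worst_action(action, act)
        rows.append((rsid, betas, ses, ns, by, float(o["se"]),
                     np.nan if pd.isna(ref_eaf) else float(ref_eaf),
                     np.nan if pd.isna(o["n"]) else float(o["n"])))

    if not rows:
        raise InputError("no SNPs survived multi-exposure harmonization")
    rsids = [r[0] for r in rows]
    return HarmonizedSet(
        rsids=rsids,
        exposure_names=[e.trait_name for e in exposures],
        exposure_beta=np.array([r[1] for r in rows], float),
        exposure_se=np.array([r[2] for r in rows], float),
        outcome_beta=np.array([r[4] for r in rows], float),
        outcome_se=np.array([r[5] for r in rows], float),
        actions=actions,
        eaf=np.array([r[6] for r in rows], float),
        exposure_n=np.array([r[3] for r in rows], float),
        outcome_n=np.array([r[7] for r in rows], float),
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
    )


_ACTION_RANK = {ACTION_KEPT: 0, ACTION_SIGN_FLIPPED: 1, ACTION_STRAND_COMPLEMENTED: 2}


def _worst_action(a: str, b: str) -> str:
    return a if _ACTION_RANK[a] >= _ACTION_RANK[b] else b
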