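"""Detection of convergent and parallel amino-acid substitutions.

The "identical" criterion: a site is called when two or more foreground
terminal branches each underwent a substitution (reconstructed parent state
differs from the tip residue) to the *exact same* derived amino acid.  The
event is classed *parallel* when all ancestral states agree, *convergent*
when they are pairwise distinct, and *mixed* otherwise.  With the
exclusivity rule switched on (the default), the derived amino acid must be
absent from every non-foreground tip at that site, and at least
``min_outgroup_residues`` non-foreground tips must actually carry a residue
there — exclusivity is not assessable on missing data.

Substitutions are assessed on terminal branches only (parent-of-tip versus
tip), matching a species-level foreground definition; sites where the
parent's reconstruction is tied are disqualified for that branch.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from .phylo_model import AncestralStateTable
from .seqio import (AA_ALPHABET, ConvergentSiteRecord, GAP, MISSING, Msa,
                    PhyloTree, STOP, ValidationError, classify_ancestors)

_STANDARD = set(AA_ALPHABET)


def branch_substitutions(
    tree: PhyloTree,
    asr: AncestralStateTable,
    msa: Msa,
    branch: str,
    site: int,
    allow_tied: bool = False,
) -> Optional[tuple[str, str, float]]:
    """Substitution on the terminal branch of tip ``branch`` at ``site`` (0-based).

    Returns ``(ancestral MAP state, derived tip residue, ancestral MAP
    posterior)`` when the two differ, the tip residue is a standard amino
    acid, and the parent's MAP is untied; otherwise ``None``.
    """
    if not 0 <= site < msa.n_columns:
        raise ValidationError(f"site {site} out of range")
    leaf = tree.find_leaf(branch)
    parent = leaf.parent
    if parent is None:
        raise ValidationError(f"tip {branch!r} has no parent branch")
    tip_state = msa.sequence(branch)[site]
    if tip_state not in _STANDARD:
        return None
    if asr.tied[parent.index][site] and not allow_tied:
        return None
    anc = asr.map_state[parent.index][site]
    if anc == tip_state:
        return None
    return anc, tip_state, float(asr.map_posterior[parent.index][site])


def scan_identical(
    tree: PhyloTree,
    asr: AncestralStateTable,
    msa: Msa,
    foreground: Iterable[str],
    require_exclusive: bool = True,
    min_outgroup_residues: int = 2,
    min_anc_posterior: float = 0.0,
    orthogroup_id: str = "OG",
) -> list[ConvergentSiteRecord]:
    """Scan every site for shared derived amino acids on foreground branches.

    For each site and derived amino acid, the *maximal* subset of foreground
    tips substituting to it is considered; a record is emitted when the
    subset has size >= 2, every ancestral MAP posterior is at least
    ``min_anc_posterior`` and, when ``require_exclusive``, no non-foreground
    tip shows the derived residue while at least ``min_outgroup_residues``
    non-foreground tips have a non-missing residue at the site.  Reported
    columns are 1-based coordinates in the original (pre-masking) alignment.
    """
    fg = sorted(set(foreground))
    if len(fg) < 2:
        raise ValidationError("need at least 2 foreground taxa")
    tips_in_tree = set(tree.leaf_labels)
    for t in fg:
        if t not in tips_in_tree:
            raise ValidationError(f"foreground taxon {t!r} not in tree")
        msa.sequence(t)  # raises KeyError-like if absent
    background = [t for t in msa.ids if t not in set(fg) and t in tips_in_tree]

    records: list[ConvergentSiteRecord] = []
    for site in range(msa.n_columns):
        by_derived: dict[str, dict[str, tuple[str, float, str]]] = defaultdict(dict)
        for taxon in fg:
            sub = branch_substitutions(tree, asr, msa, taxon, site)
            if sub is None:
                continue
            anc, derived, post = sub
            if post < min_anc_posterior:
                continue
            by_derived[derived][taxon] = (anc, post, derived)
        for derived, branches in by_derived.items():
            if len(branches) < 2:
                continue
            bg_residues = [msa.sequence(t)[site] for t in background]
            present = [r for r in bg_residues if r not in (GAP, MISSING, STOP)]
            shared_by_bg = any(r == derived for r in present)
            exclusive = (not shared_by_bg) and len(present) >= min_outgroup_residues
            if require_exclusive and not exclusive:
                continue
            records.append(ConvergentSiteRecord(
                orthogroup_id=orthogroup_id,
                column=msa.original_column(site),
                branches=branches,
                derived=derived,
                classification=classify_ancestors(
                    [a for a, _, _ in branches.values()]),
                exclusive=exclusive,
                n_outgroup_residues_checked=len(present),
            ))
    return records


def summarize_scan(
    records: Sequence[ConvergentSiteRecord],
    foreground: Iterable[str],
) -> pd.DataFrame:
    """Site and distinct-gene counts per foreground subset.

    Two counting conventions are reported for every subset of the foreground
    of size >= 2: ``exact`` (records whose subset is exactly this one) and
    ``at_least`` (records whose subset contains it) — the latter answers
    "how many sites converged in *these two* species, whether or not a third
    joined in".
    """
    from itertools import combinations

    fg = sorted(set(foreground))
    rows = []
    for size in range(2, len(fg) + 1):
        for combo in combinations(fg, size):
            combo_set = frozenset(combo)
            exact = [r for r in records if r.foreground_subset == combo_set]
            superset = [r for r in records if combo_set <= r.foreground_subset]
            rows.append({
                "subset": ",".join(combo),
                "n_taxa": size,
                "sites_exact": len(exact),
                "genes_exact": len({r.orthogroup_id for r in exact}),
                "sites_at_least": len(superset),
                "genes_at_least": len({r.orthogroup_id for r in superset}),
            })
    return pd.DataFrame(rows, columns=["subset", "n_taxa", "sites_exact",
                                       "genes_exact", "sites_at_least",
                                       "genes_at_least"])
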