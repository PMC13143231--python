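"""Ortholog delineation from gene trees and single-copy orthogroup selection.

A gene tree over sequences from several species is scanned root-ward for
maximal clades that (i) have support >= 0.95, (ii) contain each species at
most once after collapsing same-species monophyletic tip groups
("in-paralogs") into one operational unit, and (iii) cover at least four
distinct species.  From the delineated sets, orthogroups with exactly one
copy in every target (foreground) species and at least two outgroup species
are retained for downstream selection and convergence analyses.

Unlabelled internal nodes are treated as support 0 and therefore cannot
anchor a clade — a conservative convention given the >= 0.95 requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .seqio import OrthologSet, PhyloTree, TreeNode, ValidationError


@dataclass
class GeneFamilyCounts:
    """Per-species gene copy counts for one orthogroup (gene family)."""
    orthogroup_id: str
    counts: dict[str, int]

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("negative gene copy count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# Clade qualification
# ---------------------------------------------------------------------------

def _leaves_under(node: TreeNode) -> list[TreeNode]:
    out, stack = [], [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.append(cur)
        else:
            stack.extend(cur.children)
    return out


def _species_monophyletic(node: TreeNode, species_of: Mapping[str, str]) -> bool:
    """True when, below ``node``, each species' tips form a single clade.

    Checked bottom-up: a species is "resolved" at the smallest node covering
    all of its tips; at any node, an unresolved species must be the node's
    only species content.
    """
    def walk(cur: TreeNode) -> Optional[dict[str, int]]:
        # returns species -> tip count below cur, or None on violation
        if cur.is_leaf:
            return {species_of[cur.name]: 1}
        counts: dict[str, int] = {}
        child_maps = []
        for child in cur.children:
            sub = walk(child)
            if sub is None:
                return None
            child_maps.append(sub)
            for sp, c in sub.items():
                counts[sp] = counts.get(sp, 0) + c
        # a species split across >=2 children only stays monophyletic when
        # this whole subtree is that single species (pure subtrees merging)
        for sp in counts:
            holders = [m for m in child_maps if sp in m]
            if len(holders) > 1 and set(counts) != {sp}:
                return None
        return counts

    return walk(node) is not None


def clade_qualifies(
    node: TreeNode,
    species_of: Mapping[str, str],
    min_support: float = 0.95,
    min_species: int = 4,
    allow_inparalogs: bool = True,
) -> bool:
    """Apply the support / species-uniqueness / species-count rules to one clade."""
    if node.is_leaf:
        return False
    support = node.support if node.support is not None else 0.0
    if support < min_support:
        return False
    leaves = _leaves_under(node)
    for lf in leaves:
        if lf.name not in species_of:
            raise ValidationError(f"leaf {lf.name!r} has no species mapping")
    species = [species_of[lf.name] for lf in leaves]
    if len(set(species)) < min_species:
        return False
    if len(set(species)) != len(species):  # duplicated species present
        if not allow_inparalogs:
            return False
        if not _species_monophyletic(node, species_of):
            return False
    return True


def extract_ortholog_clades(
    gene_tree: PhyloTree,
    min_support: float = 0.95,
    min_species: int = 4,
    allow_inparalogs: bool = True,
    seq_lengths: Optional[Mapping[str, int]] = None,
    orthogroup_id: str = "OG",
) -> list[OrthologSet]:
    """Delineate maximal qualifying ortholog clades from a rooted gene tree.

    The tree is scanned root-ward (preorder); once a clade qualifies, its
    descendants are not scanned, so the returned sets are leaf-disjoint and
    maximal.  In-paralogs are represented by the longest member when
    ``seq_lengths`` is given, otherwise by the lexicographically smallest id.
    """
    species_of = gene_tree.species_of
    sets: list[OrthologSet] = []
    counter = 0

    def represent(members: Sequence[str]) -> str:
        if seq_lengths:
            return max(sorted(members), key=lambda m: seq_lengths.get(m, 0))
        return min(members)

    def visit(node: TreeNode):
        nonlocal counter
        if clade_qualifies(node, species_of, min_support, min_species,
                           allow_inparalogs):
            leaves = sorted(lf.name for lf in _leaves_under(node))
            counts: dict[str, int] = {}
            by_species: dict[str, list[str]] = {}
            for name in leaves:
                sp = species_of[name]
                counts[sp] = counts.get(sp, 0) + 1
                by_species.setdefault(sp, []).append(name)
            counter += 1
            sets.append(OrthologSet(
                orthogroup_id=f"{orthogroup_id}.{counter}",
                member_ids=leaves,
                copy_counts=counts,
                representatives={sp: represent(ms) for sp, ms in by_species.items()},
            ))
            return
        for child in node.children:
            visit(child)

    visit(gene_tree.root)
    return sets


def select_single_copy(
    sets: Iterable[OrthologSet],
    target_species: Iterable[str],
    min_outgroups: int = 2,
    species_universe: Optional[Iterable[str]] = None,
) -> list[OrthologSet]:
    """Keep sets with exactly one copy in every target species and enough outgroups.

    ``species_universe``, when given, is the full species set of the run;
    a target species outside it is a configuration error.
    """
    targets = set(target_species)
    if species_universe is not None:
        missing = targets - set(species_universe)
        if missing:
            raise ValidationError(
                f"target species not in run universe: {sorted(missing)}")
    out = []
    for s in sets:
        if any(s.copy_counts.get(t, 0) != 1 for t in targets):
            s.single_copy_in_targets = False
            continue
        s.single_copy_in_targets = True
        n_out = sum(1 for sp, c in s.copy_counts.items()
                    if sp not in targets and c > 0)
        if n_out >= min_outgroups:
            out.append(s)
    return out


def family_size_filter(
    families: Iterable[GeneFamilyCounts],
    max_members: int = 100,
) -> list[GeneFamilyCounts]:
    """Drop gene families with more than ``max_members`` total copies."""
    return [f for f in families if f.total <= max_members]


def read_orthogroup_counts(path) -> list[GeneFamilyCounts]:
    """Ingest an OrthoFinder-style Orthogroups.tsv into per-species counts.

    Expected layout: first column orthogroup id, remaining columns one per
    species, cells holding comma-separated member gene ids (possibly empty).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    species = list(df.columns[1:])
    out = []
    for _, row in df.iterrows():
        counts = {sp: (len([g for g in row[sp].split(",") if g.strip()])
                       if row[sp].strip() else 0)
                  for sp in species}
        out.append(GeneFamilyCounts(row[og_col], counts))
    return out
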