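"""Core domain types and I/O: trees (Newick), alignments (FASTA), site reports (TSV).

Coordinate conventions
----------------------
Alignment columns are tracked 0-based internally; every report writes the
1-based coordinate in the *original* (pre-masking) alignment, recovered via
:attr:`Msa.column_map`.  Bootstrap-style supports read from Newick internal
labels are normalised to the [0, 1] scale: values > 1 are divided by 100, so
the delineation threshold (0.95) is independent of the tree builder's
convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import dendropy
import pandas as pd

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
MISSING = "X"
STOP = "*"


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a rooted phylogeny.

    Attributes
    ----------
    name : str or None
        Leaf label (unique across leaves) or optional internal label.
    length : float
        Branch length to the parent in expected substitutions/site
        (0.0 for the root).
    support : float or None
        Support of the clade below this node, in [0, 1]; ``None`` when the
        input carried no label.
    """

    __slots__ = ("name", "length", "support", "children", "parent", "index")

    def __init__(self, name=None, length=0.0, support=None):
        self.name: Optional[str] = name
        self.length: float = length
        self.support: Optional[float] = support
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.index: int = -1  # postorder index, assigned by PhyloTree

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node


class PhyloTree:
    """Rooted tree with branch lengths, internal supports and a leaf→species map.

    The node list is kept in postorder (root last) so pruning-algorithm code
    can run as flat array passes.
    """

    def __init__(self, root: TreeNode, species_of: Optional[Mapping[str, str]] = None):
        self.root = root
        self._reindex()
        self._validate()
        # default: every leaf is its own species
        self.species_of: dict[str, str] = dict(species_of) if species_of else {
            lf.name: lf.name for lf in self.leaves()
        }

    # -- structure ---------------------------------------------------------

    def _reindex(self) -> None:
        self.nodes: list[TreeNode] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                node.index = len(self.nodes)
                self.nodes.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def _validate(self) -> None:
        labels = [n.name for n in self.nodes if n.is_leaf]
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate leaf labels: {dup}")
        if any(lbl is None for lbl in labels):
            raise ValidationError("every leaf must carry a label")
        for n in self.nodes:
            if n is not self.root and n.parent is None:
                raise ValidationError("non-root node without parent")
            if n.length < 0:
                raise ValidationError(f"negative branch length at {n.name!r}")
            if n.support is not None and not (0.0 <= n.support <= 1.0):
                raise ValidationError(f"support outside [0,1] at {n.name!r}")

    def leaves(self) -> Iterator[TreeNode]:
        return (n for n in self.nodes if n.is_leaf)

    @property
    def leaf_labels(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def postorder(self) -> Iterator[TreeNode]:
        return iter(self.nodes)

    def preorder(self) -> Iterator[TreeNode]:
        return reversed(self.nodes)

    def internal_nodes(self) -> Iterator[TreeNode]:
        return (n for n in self.nodes if not n.is_leaf)

    def find_leaf(self, label: str) -> TreeNode:
        for n in self.leaves():
            if n.name == label:
                return n
        raise KeyError(label)

    def leaf_set(self, node: TreeNode) -> frozenset[str]:
        """Labels of the leaves under ``node`` (inclusive)."""
        out, stack = [], [node]
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                out.append(cur.name)
            else:
                stack.extend(cur.children)
        return frozenset(out)

    def copy(self) -> "PhyloTree":
        return parse_newick(write_newick(self), species_of=self.species_of)

    def __len__(self) -> int:
        return sum(1 for _ in self.leaves())


def _support_from_label(label: str) -> Optional[float]:
    try:
        value = float(label)
    except (TypeError, ValueError):
        return None
    if value > 1.0:  # percentage convention
        value /= 100.0
    if value < 0.0 or value > 1.0:
        raise ValidationError(f"support {label!r} outside admissible range")
    return value


def parse_newick(text: str, species_of: Optional[Mapping[str, str]] = None) -> PhyloTree:
    """Parse a single rooted Newick string.

    Numeric internal-node labels are read as clade supports; values on the
    0–100 scale are divided by 100.  Raises :class:`ValidationError` for
    duplicate leaf labels or negative branch lengths, and a dendropy parse
    error for malformed Newick.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific classes
        if "duplicate" in str(exc).lower():
            raise ValidationError(str(exc)) from exc
        raise

    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(
            name=label,
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
        )
        if dnode.child_nodes():
            node.support = _support_from_label(dnode.label)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node), species_of=species_of)


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: PhyloTree) -> str:
    """Serialise to Newick; supports are written as internal labels in [0,1]."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{_format_length(node.length)}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:.10g}"
        if node is tree.root and node.length == 0.0:
            return f"({inner}){label}"
        return f"({inner}){label}:{_format_length(node.length)}"

    return fmt(tree.root) + ";"


def restrict_tree(tree: PhyloTree, labels: Iterable[str]) -> PhyloTree:
    """Prune the tree down to the given leaf labels (suppressing unary nodes).

    Supports and branch lengths are preserved; the length of a suppressed
    unary node is added to its child's branch.
    """
    keep = set(labels)
    missing = keep - set(tree.leaf_labels)
    if missing:
        raise ValidationError(f"labels not in tree: {sorted(missing)}")

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if node.name in keep:
                return TreeNode(node.name, node.length, node.support)
            return None
        children = [c for c in (prune(ch) for ch in node.children) if c]
        if not children:
            return None
        if len(children) == 1:
            child = children[0]
            child.length += node.length
            return child
        new = TreeNode(node.name, node.length, node.support)
        for c in children:
            new.add_child(c)
        return new

    root = prune(tree.root)
    if root is None or root.is_leaf:
        raise ValidationError("pruning left fewer than 2 leaves")
    root.length = 0.0
    species = {k: v for k, v in tree.species_of.items() if k in keep}
    return PhyloTree(root, species_of=species)


def read_species_map(path) -> dict[str, str]:
    """Read a two-column TSV (sequence id, species) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["leaf", "species"], dtype=str)
    return dict(zip(df["leaf"], df["species"]))


# ---------------------------------------------------------------------------
# Alignments and sequence sets
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """Protein multiple sequence alignment with column provenance.

    ``column_map[j]`` is the 0-based index, in the original input alignment,
    of current column ``j``.  Successive maskings compose the map, so reports
    can always cite coordinates in the alignment the user supplied.
    """

    records: list[tuple[str, str]]
    column_map: list[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.records:
            raise ValidationError("empty alignment")
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sequence ids in alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        self.records = [(i, s.upper()) for i, s in self.records]
        if self.column_map is None:
            self.column_map = list(range(self.n_columns))
        if len(self.column_map) != self.n_columns:
            raise ValidationError("column_map length mismatch")
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise ValidationError("column_map must be strictly increasing")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    def sequence(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.records)

    def original_column(self, j: int) -> int:
        """1-based coordinate of current column ``j`` in the original alignment."""
        return self.column_map[j] + 1

    def select_columns(self, keep: Sequence[int]) -> "Msa":
        keep = list(keep)
        recs = [(i, "".join(s[j] for j in keep)) for i, s in self.records]
        return Msa(recs, column_map=[self.column_map[j] for j in keep])

    def select_rows(self, keep_ids: Iterable[str]) -> "Msa":
        keep = set(keep_ids)
        recs = [(i, s) for i, s in self.records if i in keep]
        if not recs:
            raise ValidationError("row selection removed every sequence")
        return Msa(recs, column_map=list(self.column_map))

    def drop_allgap_columns(self) -> "Msa":
        keep = [j for j in range(self.n_columns)
                if any(seq[j] != GAP for _, seq in self.records)]
        return self.select_columns(keep)


@dataclass
class CdsSet:
    """Unaligned coding sequences (standard genetic code)."""

    records: list[tuple[str, str]]
    genetic_code: int = 1

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sequence ids in CDS set")
        self.records = [(i, s.upper()) for i, s in self.records]

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def sequence(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(seq_id)


@dataclass
class OrthologSet:
    """One delineated ortholog clade: members, per-species copy counts, flags."""

    orthogroup_id: str
    member_ids: list[str]
    copy_counts: dict[str, int]
    representatives: dict[str, str] = field(default_factory=dict)
    single_copy_in_targets: Optional[bool] = None

    def __post_init__(self):
        if any(c < 0 for c in self.copy_counts.values()):
            raise ValidationError("negative copy count")
        if sum(self.copy_counts.values()) != len(self.member_ids):
            raise ValidationError("copy counts do not sum to member count")

    @property
    def n_species(self) -> int:
        return sum(1 for c in self.copy_counts.values() if c > 0)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _iter_fasta(handle) -> Iterator[tuple[str, str]]:
    name, chunks = None, []
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if name is not None:
                yield name, "".join(chunks)
            name, chunks = line[1:].split()[0], []
        elif line:
            chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def read_fasta_msa(path) -> Msa:
    """Read an aligned protein FASTA; uppercases residues, requires equal lengths."""
    with open(path) as fh:
        records = list(_iter_fasta(fh))
    if not records:
        raise ValidationError(f"empty FASTA: {path}")
    return Msa(records)


def read_fasta_cds(path) -> CdsSet:
    with open(path) as fh:
        records = list(_iter_fasta(fh))
    if not records:
        raise ValidationError(f"empty FASTA: {path}")
    return CdsSet(records)


def write_fasta(obj, path, width: int = 60) -> None:
    """Write an Msa or CdsSet (or an (id, seq) iterable) as FASTA."""
    records = obj.records if hasattr(obj, "records") else list(obj)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k:k + width] + "\n")


# ---------------------------------------------------------------------------
# Convergent-site records and reports
# ---------------------------------------------------------------------------

@dataclass
class ConvergentSiteRecord:
    """One detected convergent/parallel site.

    ``branches`` maps each foreground tip label to its
    (ancestral MAP state, ancestral MAP posterior, derived tip state) triple;
    the derived state is shared across the subset by construction.
    """

    orthogroup_id: str
    column: int                      # 1-based, original alignment coordinates
    branches: dict[str, tuple[str, float, str]]
    derived: str
    classification: str              # parallel | convergent | mixed
    exclusive: bool
    n_outgroup_residues_checked: int

    def __post_init__(self):
        if len(self.branches) < 2:
            raise ValidationError("a convergence record needs >= 2 branches")
        deriveds = {d for _, _, d in self.branches.values()}
        if deriveds != {self.derived}:
            raise ValidationError("derived states disagree within record")
        if any(a == d for a, _, d in self.branches.values()):
            raise ValidationError("branch without substitution in record")
        expected = classify_ancestors([a for a, _, _ in self.branches.values()])
        if self.classification != expected:
            raise ValidationError(
                f"class {self.classification!r} inconsistent with ancestors "
                f"(expected {expected!r})")

    @property
    def foreground_subset(self) -> frozenset[str]:
        return frozenset(self.branches)


def classify_ancestors(ancestors: Sequence[str]) -> str:
    """parallel: all ancestral states equal; convergent: all pairwise distinct;
    mixed: anything in between."""
    uniq = len(set(ancestors))
    if uniq == 1:
        return "parallel"
    if uniq == len(ancestors):
        return "convergent"
    return "mixed"


_REPORT_COLUMNS = [
    "orthogroup", "column", "foreground_subset", "ancestral_states",
    "ancestral_posteriors", "derived", "class", "exclusive",
    "n_outgroup_residues_checked",
]


def site_records_frame(records: Sequence[ConvergentSiteRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        taxa = sorted(r.branches)
        rows.append({
            "orthogroup": r.orthogroup_id,
            "column": r.column,
            "foreground_subset": ",".join(taxa),
            "ancestral_states": ",".join(r.branches[t][0] for t in taxa),
            "ancestral_posteriors": ",".join(f"{r.branches[t][1]:.6f}" for t in taxa),
            "derived": r.derived,
            "class": r.classification,
            "exclusive": r.exclusive,
            "n_outgroup_residues_checked": r.n_outgroup_residues_checked,
        })
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_site_report(records: Sequence[ConvergentSiteRecord], path) -> None:
    """One TSV row per record; an empty list yields a header-only file."""
    site_records_frame(records).to_csv(path, sep="\t", index=False)


def read_site_report(path) -> list[ConvergentSiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"exclusive": bool})
    out = []
    for _, row in df.iterrows():
        taxa = str(row["foreground_subset"]).split(",")
        ancs = str(row["ancestral_states"]).split(",")
        posts = [float(x) for x in str(row["ancestral_posteriors"]).split(",")]
        branches = {t: (a, p, row["derived"]) for t, a, p in zip(taxa, ancs, posts)}
        out.append(ConvergentSiteRecord(
            orthogroup_id=row["orthogroup"],
            column=int(row["column"]),
            branches=branches,
            derived=row["derived"],
            classification=row["class"],
            exclusive=bool(row["exclusive"]),
            n_outgroup_residues_checked=int(row["n_outgroup_residues_checked"]),
        ))
    return out
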