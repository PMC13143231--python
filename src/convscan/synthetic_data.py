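"""Synthetic sequence evolution with known ground truth.

Generates everything the pipeline consumes: alignments evolved along a fixed
tree under an empirical substitution model, planted foreground-exclusive
parallel/convergent substitutions, QC contaminants (short sequences,
gap-flooded sequences, premature stop codons, in-paralog duplications in
gene trees), and Monte-Carlo null distributions of convergence counts under
purely neutral evolution — the stochastic-convergence background the scan's
calls must be judged against.

The default study design mirrors a three-order sampling: three foreground
taxa sitting in three separate clades with six outgroup taxa.  All
randomness flows from a single integer seed through numpy's Generator;
per-replicate streams are derived as ``seed + replicate`` so any subset of a
run can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .phylo_model import SubstitutionModel, load_model, marginal_asr
from .seqio import GAP, Msa, CdsSet, PhyloTree, TreeNode, ValidationError, parse_newick

#: Nine-taxon study topology: foreground taxa fg1..fg3 each nested inside a
#: different outgroup clade, echoing one adapted species per insect order.
DEFAULT_TOPOLOGY = (
    "(((fg1:0.08,out1:0.08)1.0:0.06,out2:0.14)1.0:0.05,"
    "((fg2:0.09,out3:0.09)1.0:0.05,out4:0.14)1.0:0.04,"
    "((fg3:0.07,out5:0.07)1.0:0.06,out6:0.13)1.0:0.02);"
)


@dataclass
class PlantedSite:
    """Specification of one planted convergence event.

    ``site`` is 1-based in the simulated alignment.  ``outgroup_share``
    plants a deliberately non-exclusive site (one outgroup tip also carries
    the derived residue) for false-positive accounting.
    """
    site: int
    subset: tuple[str, ...]
    derived: str
    mode: str = "parallel"        # parallel | convergent
    outgroup_share: bool = False


@dataclass
class ContaminantRates:
    short_seq: float = 0.0
    high_missing: float = 0.0
    premature_stop: float = 0.0
    inparalog: float = 0.0

    def __post_init__(self):
        for name in ("short_seq", "high_missing", "premature_stop", "inparalog"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"rate {name} outside [0,1]")


@dataclass
class SimulationConfig:
    tree: PhyloTree
    model: SubstitutionModel
    n_sites: int = 200
    seed: int = 0
    foreground: tuple[str, ...] = ("fg1", "fg2", "fg3")
    planted_sites: list[PlantedSite] = field(default_factory=list)
    contaminants: ContaminantRates = field(default_factory=ContaminantRates)

    def __post_init__(self):
        sites = [p.site for p in self.planted_sites]
        if len(sites) != len(set(sites)):
            raise ValidationError("planted sites must be distinct")
        if any(not 1 <= s <= self.n_sites for s in sites):
            raise ValidationError("planted site outside [1, n_sites]")


def default_config(seed: int = 0, n_sites: int = 200,
                   model: Optional[SubstitutionModel] = None) -> SimulationConfig:
    return SimulationConfig(
        tree=parse_newick(DEFAULT_TOPOLOGY),
        model=model if model is not None else load_model("LG"),
        n_sites=n_sites,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

def _sample_rows(P: np.ndarray, parent_states: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Child states per site given parent states and a transition matrix."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def simulate_alignment(cfg: SimulationConfig) -> tuple[Msa, dict[int, str]]:
    """Evolve ``n_sites`` independent sites along the tree.

    Root states are drawn from the stationary frequencies; each branch then
    substitutes according to P(Q t).  Returns the tip alignment and the full
    true labelling (state string per node, keyed by postorder node index —
    tips included).  Identical seeds give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    model, tree = cfg.model, cfg.tree
    k = model.n_states
    states: dict[int, np.ndarray] = {}
    cum_pi = np.cumsum(model.pi)
    states[tree.root.index] = (rng.random(cfg.n_sites)[:, None]
                               > cum_pi[None, :]).sum(axis=1)
    for node in tree.preorder():
        if node is tree.root:
            continue
        P = model.transition_matrix(node.length)
        states[node.index] = _sample_rows(P, states[node.parent.index], rng)
    truth = {idx: "".join(model.alphabet[s] for s in arr)
             for idx, arr in states.items()}
    records = [(leaf.name, truth[leaf.index]) for leaf in tree.leaves()]
    return Msa(records), truth


# ---------------------------------------------------------------------------
# Planting convergence
# ---------------------------------------------------------------------------

def _parent_truth_states(tree: PhyloTree, truth: dict[int, str],
                         subset: Iterable[str], site0: int) -> list[str]:
    return [truth[tree.find_leaf(t).parent.index][site0] for t in subset]


def _mode_ok(ancestors: list[str], derived: str, mode: str) -> bool:
    if derived in ancestors:
        return False
    if mode == "parallel":
        return len(set(ancestors)) == 1
    if mode == "convergent":
        return len(set(ancestors)) == len(ancestors)
    raise ValidationError(f"unknown planting mode {mode!r}")


def plant_convergence(
    msa: Msa,
    truth: dict[int, str],
    cfg: SimulationConfig,
    max_attempts: int = 1000,
) -> tuple[Msa, list[dict]]:
    """Overwrite foreground tips at the planted sites with the derived residue.

    Only tip states are edited; the truth labelling of ancestors refers to
    the pre-edit simulation.  For mode ``parallel`` the (true) parent states
    of the planted subset must be identical, for ``convergent`` pairwise
    distinct; a site violating its mode constraint is rejected and another
    site drawn at random, up to ``max_attempts``.  Unless
    ``outgroup_share`` is set, every non-foreground tip carrying the derived
    residue at a planted site is resampled from the stationary frequencies
    excluding it, making the planted site exclusive by construction.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    tree, model = cfg.tree, cfg.model
    seqs = {i: list(s) for i, s in msa.records}
    fg_all = set(cfg.foreground)
    used = set()
    manifest = []
    for plant in cfg.planted_sites:
        site0 = plant.site - 1
        attempts = 0
        while True:
            ancestors = _parent_truth_states(tree, truth, plant.subset, site0)
            if site0 not in used and _mode_ok(ancestors, plant.derived, plant.mode):
                break
            attempts += 1
            if attempts > max_attempts:
                raise ValidationError(
                    f"could not satisfy {plant.mode!r} constraint for "
                    f"subset {plant.subset} (derived {plant.derived!r}) "
                    f"after {max_attempts} resamples")
            site0 = int(rng.integers(0, cfg.n_sites))
        used.add(site0)
        for taxon in plant.subset:
            seqs[taxon][site0] = plant.derived
        outgroups = [t for t in msa.ids if t not in fg_all]
        if plant.outgroup_share:
            sharer = outgroups[int(rng.integers(0, len(outgroups)))]
            seqs[sharer][site0] = plant.derived
        else:
            others = [i for i, c in enumerate(model.alphabet)
                      if c != plant.derived]
            p = model.pi[others] / model.pi[others].sum()
            for taxon in outgroups:
                if seqs[taxon][site0] == plant.derived:
                    seqs[taxon][site0] = model.alphabet[
                        others[int(rng.choice(len(others), p=p))]]
        manifest.append({
            "site": site0 + 1,
            "subset": list(plant.subset),
            "derived": plant.derived,
            "mode": plant.mode,
            "outgroup_share": plant.outgroup_share,
            "true_ancestors": ancestors,
        })
    planted = Msa([(i, "".join(seqs[i])) for i in msa.ids],
                  column_map=list(msa.column_map))
    return planted, manifest


# ---------------------------------------------------------------------------
# Contaminants
# ---------------------------------------------------------------------------

def inject_contaminants(
    obj,
    cfg: SimulationConfig,
) -> tuple[object, list[dict]]:
    """Perturb an Msa or CdsSet with QC-violating records.

    Msa: with probability ``short_seq`` a record is truncated below 20
    non-gap residues; with probability ``high_missing`` it is gap-flooded to
    at least 90% missing.  CdsSet: with probability ``premature_stop`` an
    internal codon is replaced by TAA.  The manifest lists every injected
    defect; zero rates return the input unchanged.
    """
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    rates = cfg.contaminants
    manifest: list[dict] = []
    if isinstance(obj, Msa):
        rows = []
        for seq_id, seq in obj.records:
            chars = list(seq)
            if rng.random() < rates.short_seq:
                kept = 0
                for i, c in enumerate(chars):
                    if c != GAP:
                        kept += 1
                        if kept > 19:
                            chars[i] = GAP
                manifest.append({"id": seq_id, "defect": "short_seq"})
            elif rng.random() < rates.high_missing:
                n = len(chars)
                need = int(np.ceil(0.9 * n))
                present = [i for i, c in enumerate(chars) if c != GAP]
                have_missing = n - len(present)
                for i in present[:max(0, need - have_missing)]:
                    chars[i] = GAP
                manifest.append({"id": seq_id, "defect": "high_missing"})
            rows.append((seq_id, "".join(chars)))
        return Msa(rows, column_map=list(obj.column_map)), manifest
    if isinstance(obj, CdsSet):
        rows = []
        for seq_id, nt in obj.records:
            n_codons = len(nt) // 3
            if n_codons >= 3 and rng.random() < rates.premature_stop:
                pos = int(rng.integers(1, n_codons - 1))
                nt = nt[:3 * pos] + "TAA" + nt[3 * (pos + 1):]
                manifest.append({"id": seq_id, "defect": "premature_stop"})
            rows.append((seq_id, nt))
        return CdsSet(rows, genetic_code=obj.genetic_code), manifest
    raise ValidationError(f"cannot inject contaminants into {type(obj).__name__}")


def graft_inparalogs(
    tree: PhyloTree,
    cfg: SimulationConfig,
) -> tuple[PhyloTree, list[dict]]:
    """Duplicate random leaves into same-species cherries (in-paralog pairs).

    Each leaf is duplicated with probability ``inparalog``: the tip becomes a
    fully supported cherry of the original and a ``<label>.dup`` copy mapped
    to the same species.
    """
    rng = np.random.default_rng(cfg.seed + 3_000_003)
    tree = tree.copy()
    manifest = []
    for leaf in list(tree.leaves()):
        if rng.random() < cfg.contaminants.inparalog:
            dup_name = f"{leaf.name}.dup"
            original = TreeNode(leaf.name, length=0.01)
            dup = TreeNode(dup_name, length=0.01)
            species = tree.species_of[leaf.name]
            leaf.name = None
            leaf.support = 1.0
            leaf.add_child(original)
            leaf.add_child(dup)
            tree.species_of[dup_name] = species
            manifest.append({"id": original.name, "defect": "inparalog",
                             "duplicate": dup_name})
    rebuilt = PhyloTree(tree.root, species_of=tree.species_of)
    return rebuilt, manifest


# ---------------------------------------------------------------------------
# Whole-dataset emission
# ---------------------------------------------------------------------------

def write_synthetic_dataset(
    out_dir,
    n_orthogroups: int = 20,
    n_planted_genes: int = 5,
    sites_per_gene: int = 200,
    plants_per_gene: int = 2,
    seed: int = 0,
    model: Optional[SubstitutionModel] = None,
    derived: str = "N",
    mode: str = "parallel",
) -> dict:
    """Emit a multi-orthogroup dataset (FASTA + Newick + truth manifest).

    The first ``n_planted_genes`` orthogroups carry ``plants_per_gene``
    exclusive 3-way convergent/parallel sites; the rest evolve neutrally.
    Per-orthogroup seeds are ``seed + index`` so any single orthogroup can be
    regenerated alone.  Returns the truth manifest (also written as
    ``truth.json``).
    """
    import json
    from pathlib import Path

    from .seqio import write_fasta, write_newick

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = load_model("LG")
    truth_manifest: dict = {"seed": seed, "orthogroups": {}}
    for idx in range(n_orthogroups):
        og = f"og{idx:04d}"
        cfg = default_config(seed=seed + idx, n_sites=sites_per_gene,
                             model=model)
        plants = []
        if idx < n_planted_genes:
            rng = np.random.default_rng(seed + idx + 5_000_011)
            sites = 1 + rng.choice(sites_per_gene, size=plants_per_gene,
                                   replace=False)
            plants = [PlantedSite(int(s), cfg.foreground, derived, mode)
                      for s in sorted(sites)]
        cfg = replace(cfg, planted_sites=plants)
        msa, truth = simulate_alignment(cfg)
        if plants:
            msa, manifest = plant_convergence(msa, truth, cfg)
        else:
            manifest = []
        write_fasta(msa, out / f"{og}.faa")
        (out / f"{og}.nwk").write_text(write_newick(cfg.tree) + "\n")
        truth_manifest["orthogroups"][og] = {
            "planted": manifest,
            "foreground": list(cfg.foreground),
        }
    (out / "truth.json").write_text(
        json.dumps(truth_manifest, indent=2, sort_keys=True) + "\n")
    return truth_manifest


# ---------------------------------------------------------------------------
# Neutral null distribution
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    counts: np.ndarray
    mean: float
    quantiles: dict[str, float]

    def empirical_p(self, observed: int) -> float:
        """Fraction of neutral replicates with a count >= observed."""
        return float(np.mean(self.counts >= observed))


def null_convergence_distribution(
    cfg: SimulationConfig,
    n_reps: int,
    **scan_kwargs,
) -> NullDistribution:
    """Monte-Carlo null of the convergence-scan count under neutral evolution.

    Each replicate simulates an alignment (no planting), reconstructs
    ancestral states and runs the scan; the count of emitted records per
    replicate forms the null distribution against which an observed
    convergence count can be given an empirical p-value.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if cfg.planted_sites:
        raise ValidationError("null distribution requires a cfg without planting")
    from .convergence import scan_identical

    counts = np.zeros(n_reps, dtype=int)
    for rep in range(n_reps):
        rep_cfg = replace(cfg, seed=cfg.seed + rep, planted_sites=[])
        msa, _ = simulate_alignment(rep_cfg)
        asr = marginal_asr(cfg.tree, msa, cfg.model)
        records = scan_identical(cfg.tree, asr, msa, list(cfg.foreground),
                                 **scan_kwargs)
        counts[rep] = len(records)
    qs = np.quantile(counts, [0.5, 0.9, 0.95, 0.99])
    return NullDistribution(
        counts=counts,
        mean=float(counts.mean()),
        quantiles={"q50": qs[0], "q90": qs[1], "q95": qs[2], "q99": qs[3]},
    )
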