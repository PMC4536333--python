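"""Synthetic-data generators.

Every analysis stage in this package is exercised on data produced here:
codon alignments evolved along a phylogeny under neutral, purifying, site,
and branch-site selection regimes; multi-species gene sets with planted
duplications at chosen species-tree branches (duplicate protein divergence
tuned into a requested percent band); similarity hit tables consistent with
the planted families; protein alignments with planted lineage-unique
residues; transposable-element class-count tables; and per-gene read counts.

All generators are pure functions of (spec, seed): the same seed yields
byte-identical output.  Alignments are generated without indels, so the
true alignment is known and gene trees record every planted event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codonmodel import (
    CodonAlignment,
    EigenQ,
    SiteClass,
    class_time_scalings,
    codon_space,
    rate_matrix,
    uniform_frequencies,
)
from .genetics import translate_cds, CdsRecord
from .selection import build_site_classes
from .trees import PhyloTree, TreeNode

#: default synthetic study phylogeny: the 8 mammal species of the expansion
#: analysis with smooth branch lengths (expected substitutions per codon).
DEFAULT_STUDY_TREE = (
    "(mm_oanatinus5:0.45,((mm_cfamiliaris3:0.18,(mm_btaurus:0.12,"
    "(mm_ttruncatus:0.06,(mm_balaenoptera:0.03,mm_bmysticetus:0.03):0.03)"
    ":0.05):0.05):0.08,(mm_hsapiens10:0.12,mm_mmusculus5:0.25):0.08):0.25);"
)

FOCAL_SPECIES = "mm_bmysticetus"

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# codon alignment simulation


@dataclass
class SimulationSpec:
    """Conditions for simulating one codon alignment."""

    tree: PhyloTree
    model: str
    n_codons: int
    seed: int
    kappa: float = 2.0
    theta: dict[str, float] = field(default_factory=dict)
    pi: np.ndarray | None = None  # default uniform over sense codons

    def site_classes(self) -> list[SiteClass]:
        return build_site_classes(self.model, self.theta)


def _sample_rows(p_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical sample per row of a probability matrix."""
    cum = np.cumsum(p_rows, axis=1)
    u = rng.random(p_rows.shape[0])
    return np.minimum((cum < u[:, None]).sum(axis=1), p_rows.shape[1] - 1)


def simulate_codon_alignment(
    spec: SimulationSpec,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codon sites along the tree; returns (alignment, site class labels).

    Each site keeps its class across the whole tree; on branches flagged as
    foreground the class's foreground omega applies, elsewhere its background
    omega — the generative reading of the branch-site model.
    """
    rng = np.random.default_rng(spec.seed)
    space = codon_space()
    pi = spec.pi if spec.pi is not None else uniform_frequencies(space)
    classes = spec.site_classes()
    props = np.array([c.proportion for c in classes])
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    labels = rng.choice(len(classes), size=spec.n_codons, p=props)
    root_states = rng.choice(space.n, size=spec.n_codons, p=pi)
    scale_bg, scale_fg = class_time_scalings(classes, spec.kappa, pi, space)

    eigen_cache: dict[float, EigenQ] = {}

    def eigen(omega: float) -> EigenQ:
        if omega not in eigen_cache:
            eigen_cache[omega] = EigenQ.decompose(
                rate_matrix(spec.kappa, omega, pi, space), pi
            )
        return eigen_cache[omega]

    states: dict[int, np.ndarray] = {id(spec.tree.root): root_states}
    for node in spec.tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        t = node.length if node.length is not None else 0.0
        child = np.empty_like(parent_states)
        for ci, cls_ in enumerate(classes):
            sites = np.nonzero(labels == ci)[0]
            if sites.size == 0:
                continue
            if node.foreground:
                omega, s = cls_.omega_foreground, scale_fg[ci]
            else:
                omega, s = cls_.omega_background, scale_bg[ci]
            p = eigen(omega).transition_matrix(t * s)
            child[sites] = _sample_rows(p[parent_states[sites]], rng)
        states[id(node)] = child

    leaves = spec.tree.root.leaves()
    matrix = np.stack([states[id(leaf)] for leaf in leaves])
    aln = CodonAlignment([leaf.name for leaf in leaves], matrix, space)
    return aln, labels


# ---------------------------------------------------------------------------
# gene family simulation with planted duplications


@dataclass
class DuplicationEvent:
    """A planted duplication on a species-tree branch.

    ``branch`` is a leaf name or a set of leaf names (the branch above their
    MRCA).
    """

    branch: str | frozenset[str]

    def resolve(self, species_tree: PhyloTree) -> TreeNode:
        if isinstance(self.branch, str):
            return species_tree.find_leaf(self.branch)
        return species_tree.mrca(set(self.branch))


@dataclass
class FamilySimSpec:
    """Conditions for simulating one gene family across species."""

    species_tree: PhyloTree
    family_id: str
    n_codons: int
    seed: int
    events: list[DuplicationEvent] = field(default_factory=list)
    kappa: float = 2.0
    omega: float = 0.2
    divergence_band: tuple[float, float] = (1.0, 10.0)
    rate_scale: float = 1.0


@dataclass
class SimulatedFamily:
    family_id: str
    gene_tree: PhyloTree
    cds: list[CdsRecord]
    proteins: dict[str, str]
    species_of: dict[str, str]
    n_planted_events: int
    event_branches: list[str]


def _gene_label(species: str, family_id: str, copy: int) -> str:
    return f"{species}|{family_id}c{copy}"


def simulate_family_evolution(spec: FamilySimSpec) -> SimulatedFamily:
    """Simulate one family: gene tree with planted duplications, CDS, proteins.

    The gene tree starts as a copy of the species tree; each planted event
    splits the corresponding branch with a duplication node whose two
    children carry identical subtrees.  Branch lengths below the duplication
    are tuned (by bisection on a scale factor, resimulating) so the most
    recent duplicate pair differs in protein sequence within the requested
    percent band.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.divergence_band
    event_nodes = [ev.resolve(spec.species_tree) for ev in spec.events]
    event_branch_names = [
        n.name if n.name else "+".join(sorted(l.name for l in n.leaves()))
        for n in event_nodes
    ]
    for node in event_nodes:
        if node.parent is not None and (node.length or 0.0) <= 0 and lo > 0:
            raise ValueError(
                f"cannot plant a divergent duplicate on zero-length branch "
                f"{node.name!r}"
            )

    scale = 1.0
    sub_seed = int(rng.integers(2**31 - 1))
    for _ in range(40):
        family = _build_and_simulate(spec, scale, sub_seed)
        if not spec.events:
            return family
        d = _max_pair_divergence(family)
        if lo <= d <= hi:
            return family
        scale *= 2.0 if d < lo else 0.5
        if not (1e-6 < scale < 1e6):
            raise ValueError("divergence band unreachable on this tree")
    raise ValueError(
        f"could not tune duplicate divergence into [{lo}, {hi}]% "
        f"(last={d:.2f}%)"
    )


def _build_and_simulate(
    spec: FamilySimSpec, dup_scale: float, seed: int
) -> SimulatedFamily:
    species_tree = spec.species_tree
    gene_root = _clone_scaled(species_tree.root, spec.rate_scale)

    # match cloned nodes to species-tree nodes by preorder position
    clone_by_orig = {
        id(o): c
        for o, c in zip(species_tree.root.preorder(), gene_root.preorder())
    }

    def depth(node: TreeNode) -> int:
        d = 0
        while node.parent is not None:
            node, d = node.parent, d + 1
        return d

    # plant ancestral events first so a later (more terminal) event lands in
    # the original lineage only, keeping one reconciliation event per plant
    ordered = sorted(spec.events, key=lambda ev: depth(ev.resolve(species_tree)))
    for ev in ordered:
        orig = ev.resolve(species_tree)
        node = clone_by_orig[id(orig)]
        _plant_duplication(node, dup_scale)

    # name gene-tree leaves species|family|copy
    copy_counter: dict[str, int] = {}
    species_of: dict[str, str] = {}
    for leaf in gene_root.leaves():
        sp = leaf.name
        copy_counter[sp] = copy_counter.get(sp, 0) + 1
        label = _gene_label(sp, spec.family_id, copy_counter[sp])
        leaf.name = label
        species_of[label] = sp

    gene_tree = PhyloTree(gene_root)
    sim = SimulationSpec(
        tree=gene_tree,
        model="M0",
        theta={"omega": spec.omega},
        kappa=spec.kappa,
        n_codons=spec.n_codons,
        seed=seed,
    )
    aln, _ = simulate_codon_alignment(sim)
    cds_records = [
        CdsRecord(gene_id=name, species=species_of[name], sequence=seq)
        for name, seq in aln.to_sequences()
    ]
    proteins = {
        rec.gene_id: translate_cds(rec).protein for rec in cds_records
    }
    event_nodes = [ev.resolve(species_tree) for ev in spec.events]
    return SimulatedFamily(
        family_id=spec.family_id,
        gene_tree=gene_tree,
        cds=cds_records,
        proteins=proteins,
        species_of=species_of,
        n_planted_events=len(spec.events),
        event_branches=[
            n.name if n.name else "+".join(sorted(l.name for l in n.leaves()))
            for n in event_nodes
        ],
    )


def _clone_scaled(node: TreeNode, scale: float) -> TreeNode:
    new = TreeNode(node.name, None if node.length is None else node.length * scale)
    for child in node.children:
        new.add_child(_clone_scaled(child, scale))
    return new


def _plant_duplication(node: TreeNode, dup_scale: float) -> None:
    """Split the branch above ``node`` with a duplication node."""
    if node.parent is None:
        raise ValueError("cannot plant a duplication above the root")
    length = node.length or 0.0
    parent = node.parent
    dup = TreeNode(name=None, length=length * 0.5)
    idx = parent.children.index(node)
    parent.children[idx] = dup
    dup.parent = parent
    copy = _clone_scaled(node, dup_scale)
    node.length = length * 0.5
    copy.length = length * 0.5 * dup_scale
    dup.add_child(node)
    dup.add_child(copy)


def percent_protein_difference_ungapped(a: str, b: str) -> float:
    """Percent mismatches between two equal-length ungapped proteins."""
    if len(a) != len(b) or not a:
        raise ValueError("proteins must be equal-length and nonempty")
    mism = sum(1 for x, y in zip(a, b) if x != y)
    return 100.0 * mism / len(a)


def _max_pair_divergence(family: SimulatedFamily) -> float:
    """Protein divergence of the closest duplicate pair per duplicated species."""
    by_species: dict[str, list[str]] = {}
    for gene, sp in family.species_of.items():
        by_species.setdefault(sp, []).append(gene)
    divs = []
    for genes in by_species.values():
        if len(genes) < 2:
            continue
        best = min(
            percent_protein_difference_ungapped(
                family.proteins[a], family.proteins[b]
            )
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
        )
        divs.append(best)
    if not divs:
        raise ValueError("no duplicate pair present")
    return max(divs)


# ---------------------------------------------------------------------------
# hit tables from simulated families


def hit_table_for_families(families: Sequence[SimulatedFamily]) -> pd.DataFrame:
    """Noise-free all-vs-all cross-species hit rows within each family.

    Percent identity is the realized protein identity; bit score scales with
    identity times length, so the best hit of every gene is its nearest
    relative and reciprocal best hits recover the planted orthology.
    """
    rows = []
    for fam in families:
        genes = sorted(fam.proteins)
        for qi in genes:
            for si in genes:
                if qi == si or fam.species_of[qi] == fam.species_of[si]:
                    continue
                a, b = fam.proteins[qi], fam.proteins[si]
                ident = 100.0 - percent_protein_difference_ungapped(a, b)
                length = len(a)
                bit = round(2.0 * length * ident / 100.0, 1)
                evalue = float(np.exp(-min(bit, 500.0)))
                rows.append(
                    (qi, si, round(ident, 2), length, 0, 0, 1, length, 1, length,
                     evalue, bit)
                )
    from .seqio import HIT_COLUMNS

    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# residue fixtures


def make_residue_fixture(
    n_species: int = 10,
    length: int = 60,
    planted_unique_positions: Sequence[int] = (),
    planted_unknowns: Sequence[int] = (),
    planted_gaps: Sequence[int] = (),
    focal: str = "bowhead",
    seed: int = 0,
) -> list[tuple[str, str]]:
    """A protein MSA where exactly the planted columns are focal-unique.

    ``planted_unique_positions``: 1-based columns where the focal sequence
    carries a residue absent from all other species (one other species is
    given an X, which the rule allows).  ``planted_unknowns``: decoy columns
    where the focal residue differs but two other species are X (rejected).
    ``planted_gaps``: decoy columns containing a gap (rejected).  All other
    columns are identical across species (focal residue present elsewhere).
    """
    uniq, unk, gaps = (
        set(planted_unique_positions),
        set(planted_unknowns),
        set(planted_gaps),
    )
    for name, positions in (
        ("unique", uniq), ("unknown", unk), ("gap", gaps),
    ):
        bad = [p for p in positions if not 1 <= p <= length]
        if bad:
            raise ValueError(f"{name} positions out of range: {bad}")
    if (uniq & unk) or (uniq & gaps) or (unk & gaps):
        raise ValueError("planted column sets overlap")
    if n_species < 3:
        raise ValueError("need the focal species plus at least two others")

    rng = np.random.default_rng(seed)
    others = [f"sp{i}" for i in range(1, n_species)]
    cols: dict[str, list[str]] = {focal: [], **{o: [] for o in others}}
    for pos in range(1, length + 1):
        base = _AA20[rng.integers(0, 20)]
        alt = _AA20[(int(_AA20.index(base)) + 1 + int(rng.integers(0, 18))) % 20]
        if pos in uniq:
            cols[focal].append(alt)
            for i, o in enumerate(others):
                cols[o].append("X" if i == 0 else base)
        elif pos in unk:
            cols[focal].append(alt)
            for i, o in enumerate(others):
                cols[o].append("X" if i < 2 else base)
        elif pos in gaps:
            cols[focal].append(alt)
            for i, o in enumerate(others):
                cols[o].append("-" if i == 0 else base)
        else:
            cols[focal].append(base)
            for o in others:
                cols[o].append(base)
    return [(name, "".join(chars)) for name, chars in cols.items()]


# ---------------------------------------------------------------------------
# TE tables and read counts


def make_te_table(
    class_props: dict[str, float], total: int, seed: int = 0
) -> dict[str, int]:
    """Multinomial transposable-element class counts."""
    props = np.array(list(class_props.values()), dtype=float)
    if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total, props)
    return dict(zip(class_props.keys(), (int(c) for c in counts)))


def _selection_family(
    family_id: str,
    species_tree: PhyloTree,
    focal_species: str,
    n_codons: int,
    seed: int,
    theta: dict[str, float],
    model: str = "A",
    kappa: float = 2.0,
) -> SimulatedFamily:
    """A one-to-one family evolved under a branch-site regime on the focal
    terminal branch (used to plant a positive-selection signal)."""
    gene_root = _clone_scaled(species_tree.root, 1.0)
    species_of: dict[str, str] = {}
    for leaf in gene_root.leaves():
        sp = leaf.name
        label = _gene_label(sp, family_id, 1)
        leaf.name = label
        species_of[label] = sp
    gene_tree = PhyloTree(gene_root)
    gene_tree.set_foreground(_gene_label(focal_species, family_id, 1))
    sim = SimulationSpec(
        tree=gene_tree, model=model, theta=theta, kappa=kappa,
        n_codons=n_codons, seed=seed,
    )
    aln, _ = simulate_codon_alignment(sim)
    gene_tree.clear_foreground()
    cds_records = [
        CdsRecord(gene_id=name, species=species_of[name], sequence=seq)
        for name, seq in aln.to_sequences()
    ]
    proteins = {rec.gene_id: translate_cds(rec).protein for rec in cds_records}
    return SimulatedFamily(
        family_id=family_id, gene_tree=gene_tree, cds=cds_records,
        proteins=proteins, species_of=species_of,
        n_planted_events=0, event_branches=[],
    )


#: synthetic sequencing-library totals (Gb) for the coverage summary
DEFAULT_LIBRARIES = [
    ("200 bp paired-end", 149.1),
    ("500 bp paired-end", 141.7),
    ("3 kb mate-paired", 57.3),
    ("5 kb mate-paired", 72.5),
    ("10 kb mate-paired", 28.5),
]

#: SINE-poor, LINE-dominated repeat landscape typical of baleen whale genomes
DEFAULT_TE_PROPS = {
    "LINE": 0.66, "SINE": 0.01, "LTR": 0.17, "DNA": 0.12, "Other": 0.04,
}


def write_bundle(
    out_dir,
    seed: int = 1,
    n_codons: int = 150,
    n_background_families: int = 5,
    focal_species: str = FOCAL_SPECIES,
) -> dict:
    """Write a complete synthetic study directory and return its truth record.

    The bundle contains: the species tree; CDS and protein FASTA for a set
    of gene families (background purifying families, one family with a
    planted branch-site positive-selection signal on the focal terminal
    branch, two families with planted focal duplications inside the 1-10%
    divergence band, one family duplicated on another branch); a noise-free
    hit table; true gene trees; read counts; a TE class-count table; and
    sequencing-library totals.
    """
    import json
    from pathlib import Path

    from .seqio import FastaRecord, write_fasta, write_hit_table

    out = Path(out_dir)
    (out / "gene_trees").mkdir(parents=True, exist_ok=True)
    (out / "residue_alignments").mkdir(exist_ok=True)

    rng = np.random.default_rng(seed)
    species_tree = PhyloTree.from_newick(DEFAULT_STUDY_TREE)
    species_tree.write(out / "species_tree.nwk")

    families: list[SimulatedFamily] = []
    truth: dict = {"seed": seed, "families": {}}

    def record(fam: SimulatedFamily, kind: str, **extra) -> None:
        families.append(fam)
        truth["families"][fam.family_id] = {
            "kind": kind,
            "n_planted_duplications": fam.n_planted_events,
            "event_branches": fam.event_branches,
            **extra,
        }

    for i in range(n_background_families):
        spec = FamilySimSpec(
            species_tree=species_tree,
            family_id=f"bg{i:02d}",
            n_codons=n_codons,
            seed=int(rng.integers(2**31 - 1)),
            omega=0.2,
        )
        record(simulate_family_evolution(spec), "background", omega=0.2)

    sel_theta = {"q": 0.9, "r": 0.5, "omega0": 0.2, "omega2": 4.0}
    fam = _selection_family(
        "possel", species_tree, focal_species, n_codons,
        int(rng.integers(2**31 - 1)), sel_theta,
    )
    record(fam, "positive_selection", theta=sel_theta)

    for i in range(2):
        spec = FamilySimSpec(
            species_tree=species_tree,
            family_id=f"dupfocal{i}",
            n_codons=n_codons,
            seed=int(rng.integers(2**31 - 1)),
            events=[DuplicationEvent(branch=focal_species)],
            omega=0.2,
        )
        record(simulate_family_evolution(spec), "focal_duplication")

    spec = FamilySimSpec(
        species_tree=species_tree,
        family_id="dupother",
        n_codons=n_codons,
        seed=int(rng.integers(2**31 - 1)),
        events=[DuplicationEvent(branch="mm_hsapiens10")],
        omega=0.2,
    )
    record(simulate_family_evolution(spec), "other_duplication")

    all_cds = [c for fam in families for c in fam.cds]
    write_fasta(
        [FastaRecord(c.gene_id, c.sequence, c.species) for c in all_cds],
        out / "cds.fasta",
    )
    write_fasta(
        [
            FastaRecord(g, p, fam.species_of[g])
            for fam in families
            for g, p in sorted(fam.proteins.items())
        ],
        out / "proteins.fasta",
    )
    write_hit_table(hit_table_for_families(families), out / "hits.tsv")
    for fam in families:
        fam.gene_tree.write(out / "gene_trees" / f"{fam.family_id}.nwk")

    gene_ids = sorted(c.gene_id for c in all_cds)
    counts = make_read_counts(
        gene_ids, seed=int(rng.integers(2**31 - 1)), fraction_silent=0.1
    )
    counts.to_csv(out / "read_counts.tsv", sep="\t", index=False)

    te_counts = make_te_table(
        DEFAULT_TE_PROPS, total=100_000, seed=int(rng.integers(2**31 - 1))
    )
    with open(out / "te_counts.tsv", "w") as fh:
        fh.write("class\tcount\n")
        for name, count in te_counts.items():
            fh.write(f"{name}\t{count}\n")
    truth["te_props"] = DEFAULT_TE_PROPS

    with open(out / "coverage.tsv", "w") as fh:
        fh.write("library\ttotal_gb\n")
        for name, total in DEFAULT_LIBRARIES:
            fh.write(f"{name}\t{total}\n")

    residue_truth = {}
    plants = {"protA": ([5, 20, 41], [11], [30]), "protB": ([7], [], []),
              "protC": ([], [15], [2])}
    for prot, (uniq, unk, gaps) in plants.items():
        msa = make_residue_fixture(
            n_species=10, length=60,
            planted_unique_positions=uniq, planted_unknowns=unk,
            planted_gaps=gaps, focal=focal_species,
            seed=int(rng.integers(2**31 - 1)),
        )
        write_fasta(
            [FastaRecord(n, s) for n, s in msa],
            out / "residue_alignments" / f"{prot}.faa",
        )
        residue_truth[prot] = {"planted_unique": uniq}
    truth["residues"] = residue_truth

    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def make_read_counts(
    gene_ids: Sequence[str],
    tissues: Sequence[str] = ("muscle", "kidney", "heart", "retina"),
    mean_expressed: float = 40.0,
    fraction_silent: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene, per-tissue read counts; a fraction of genes is silent."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene in gene_ids:
        silent = rng.random() < fraction_silent
        for tissue in tissues:
            lam = 0.2 if silent else mean_expressed / len(tissues)
            rows.append((gene, tissue, int(rng.poisson(lam))))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "count"])
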