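"""Forward simulator for codon sequences evolving along a species tree, with
optional horizontal transfers between contemporaneous lineages.

The generator produces exactly the data structure the analysis assumes: host
nuclear genes evolving strictly vertically (one ortholog per species) and TE
copies evolving vertically except for specified horizontal transfer events, at
a controlled synonymous rate. The codon process is accept/reject: proposals
are single-nucleotide changes arriving as a Poisson process calibrated so that
the accepted synonymous substitution rate is ``syn_rate`` per synonymous site
per Myr per lineage; synonymous proposals are always accepted, nonsynonymous
ones with probability ``omega`` (purifying selection), and proposals creating
stop codons are rejected. No indels are simulated, so tip sequences are
already a trivially valid codon alignment.

Defaults mirror the empirical setting the pipeline targets: Drosophilidae-like
species trees a few tens of Myr deep, RT-domain-sized fragments of ~300
codons, a synonymous rate of 0.016 substitutions/site/Myr per lineage, and
strong purifying selection (omega = 0.1) on the reverse-transcriptase protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from httscan.core_io import SequenceRecord, write_fasta
from httscan.distances import BASES, GENETIC_CODE, SENSE_CODONS, STOP_CODONS

__all__ = [
    "HttEvent",
    "SimTruth",
    "simulate_tree",
    "evolve_codon_alignment",
    "simulate_htt_dataset",
    "write_dataset",
]

DEFAULT_SYN_RATE = 0.016   # subs / synonymous site / Myr / lineage
DEFAULT_OMEGA = 0.1        # nonsynonymous acceptance probability
DEFAULT_N_CODONS = 300     # RT-domain-sized fragment

GENE_NAMES = ("Adh", "Amd", "Ddc")


@dataclass(frozen=True)
class HttEvent:
    """One horizontal transfer: a TE copy jumps from the donor lineage into
    the recipient lineage ``time_mya`` million years before present and then
    evolves in the recipient."""

    donor: str
    recipient: str
    time_mya: float
    copy_id: str

    def __post_init__(self) -> None:
        if self.time_mya < 0:
            raise ValueError("event time must be >= 0 (Mya)")
        if self.donor == self.recipient:
            raise ValueError("donor and recipient species must differ")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated dataset."""

    species_tree: dendropy.Tree
    htt_events: tuple[HttEvent, ...] = ()
    syn_rate: float = DEFAULT_SYN_RATE
    omega: float = DEFAULT_OMEGA
    n_codons: int = DEFAULT_N_CODONS
    seed: int = 0
    copies_per_species: int = 1
    copy_age_mya: float = 1.0   # duplication age of extra within-species copies

    def __post_init__(self) -> None:
        if self.syn_rate <= 0:
            raise ValueError("syn_rate must be > 0")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError("omega must be in [0, 1]")
        if self.n_codons < 1 or self.copies_per_species < 1:
            raise ValueError("n_codons and copies_per_species must be >= 1")


def simulate_tree(n_species: int, depth_myr: float,
                  seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) species tree rescaled to a fixed root-to-tip depth.

    The returned tree is ultrametric with branch lengths in Myr and tip labels
    ``sp1..spN``; identical seeds give identical newick strings.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if depth_myr <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng([seed, 0x5EED])
    # forward Yule process, birth rate 1 per lineage: the root splits at time
    # 0; while k lineages exist the next split waits Exp(k); each split picks
    # a uniformly random extant lineage
    root = dendropy.Node()
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    for k in range(2, n_species):
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(len(active)))
        parent, start = active.pop(i)
        node = dendropy.Node()
        parent.add_child(node)
        node.edge.length = t - start
        active.extend([(node, t), (node, t)])
    t_present = t + rng.exponential(1.0 / n_species)
    taxa = dendropy.TaxonNamespace([f"sp{i + 1}" for i in range(n_species)])
    for i, (parent, start) in enumerate(active):
        leaf = dendropy.Node()
        leaf.taxon = taxa[i]
        parent.add_child(leaf)
        leaf.edge.length = t_present - start
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    scale = depth_myr / t_present
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
    tree.seed_node.edge.length = None
    return tree


def _node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Ages (Myr before present) assuming an ultrametric tree."""
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    total = max(d for n, d in depth.items() if n.is_leaf())
    return {n: total - d for n, d in depth.items()}


# ---------------------------------------------------------------------------
# codon accept/reject process


def _random_root(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return [SENSE_CODONS[i] for i in idx]


def _evolve_segment(codons: list[str], duration: float, syn_rate: float,
                    omega: float, rng: np.random.Generator) -> list[str]:
    """Evolve a codon sequence for ``duration`` Myr.

    Proposals arrive at total rate 3 L_nt/3... precisely: lambda = 3 * C *
    syn_rate proposals per Myr over the whole sequence (C codons), which makes
    the accepted synonymous rate exactly syn_rate per synonymous site
    regardless of composition, because a uniform proposal is synonymous with
    probability S_current / (3 C).
    """
    if duration < 0:
        raise ValueError("negative branch duration")
    codons = list(codons)
    n_nt = 3 * len(codons)
    lam = n_nt * syn_rate * duration
    n_events = rng.poisson(lam)
    for _ in range(n_events):
        pos = int(rng.integers(n_nt))
        ci, within = divmod(pos, 3)
        codon = codons[ci]
        old = codon[within]
        alts = [b for b in BASES if b != old]
        new = alts[int(rng.integers(3))]
        mutant = codon[:within] + new + codon[within + 1:]
        if mutant in STOP_CODONS:
            continue
        if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
            codons[ci] = mutant
        elif rng.random() < omega:
            codons[ci] = mutant
    return codons


def evolve_codon_alignment(tree: dendropy.Tree, n_codons: int,
                           syn_rate: float, omega: float,
                           seed: int) -> list[SequenceRecord]:
    """Evolve one sequence per tip along the tree; returns ungapped, equal
    length tip sequences labelled by taxon. Deterministic for a fixed seed."""
    tips, _ = _evolve_tree(tree, n_codons, syn_rate, omega, seed)
    return [SequenceRecord(id=label, seq="".join(codons), species=label)
            for label, codons in tips]


def _evolve_tree(tree: dendropy.Tree, n_codons: int, syn_rate: float,
                 omega: float, seed: int, *,
                 captures: dict[str, list[tuple[int, float]]] | None = None,
                 ) -> tuple[list[tuple[str, list[str]]], dict[int, list[str]]]:
    """Core recursion. ``captures`` maps species label -> [(slot, age_mya)]
    requests for the lineage state on the terminal branch at the given age.

    Returns ``(tips, captured)``: tips as [(tip_label, codons)] in preorder
    order, captured as {slot: codons}. Per-branch RNG streams derived from
    (seed, preorder node index) keep every output deterministic.
    """
    captures = captures or {}
    ages = _node_ages(tree)
    node_index = {node: i for i, node in enumerate(tree.preorder_node_iter())}

    def branch_rng(node: dendropy.Node) -> np.random.Generator:
        return np.random.default_rng([seed, 1, node_index[node]])

    root_rng = np.random.default_rng([seed, 0])
    captured: dict[int, list[str]] = {}
    tips: list[tuple[str, list[str]]] = []

    def visit(node: dendropy.Node, codons: list[str]) -> None:
        for child in node.child_nodes():
            rng = branch_rng(child)
            start_age = ages[node]
            end_age = ages[child]
            label = child.taxon.label if child.is_leaf() else None
            wanted = (sorted(captures.get(label, []),
                             key=lambda sa: -sa[1])
                      if label is not None else [])
            seq = codons
            cur_age = start_age
            for slot, cap_age in wanted:
                cap_age = min(cap_age, start_age)
                seq = _evolve_segment(seq, cur_age - cap_age, syn_rate,
                                      omega, rng)
                captured[slot] = list(seq)
                cur_age = cap_age
            seq = _evolve_segment(seq, cur_age - end_age, syn_rate, omega, rng)
            if child.is_leaf():
                tips.append((label, seq))
            else:
                visit(child, seq)

    root_codons = _random_root(n_codons, root_rng)
    visit(tree.seed_node, root_codons)
    return tips, captured


def simulate_htt_dataset(truth: SimTruth) -> tuple[
        list[SequenceRecord], dict[str, list[SequenceRecord]], str,
        list[dict]]:
    """Simulate TE copies and host-gene orthologs under the given truth.

    Returns ``(te_records, gene_records, species_tree_newick, truth_rows)``.
    Genes evolve once each along the species tree (one ortholog per species,
    ids ``<species>_<gene>``). TE copies evolve along the species tree too;
    each transfer event grafts the donor lineage's state at ``time_mya`` into
    the recipient, where it evolves to the present (id
    ``<recipient>_h<copy_id>``). Extra within-species vertical copies (when
    ``copies_per_species > 1``) duplicate ``copy_age_mya`` before present.
    Outputs are byte-deterministic for a fixed seed.
    """
    tree = truth.species_tree
    ages = _node_ages(tree)
    terminal_start = {leaf.taxon.label: ages[leaf.parent_node]
                      for leaf in tree.leaf_node_iter()}
    for ev in truth.htt_events:
        for sp in (ev.donor, ev.recipient):
            if sp not in terminal_start:
                raise ValueError(f"unknown species {sp!r} in event {ev}")
        limit = min(terminal_start[ev.donor], terminal_start[ev.recipient])
        if ev.time_mya > limit:
            raise ValueError(
                f"event time {ev.time_mya} Mya outside the common duration of "
                f"the {ev.donor} and {ev.recipient} terminal lineages "
                f"(<= {limit:.4g} Mya)")

    # genes: vertical only
    gene_records: dict[str, list[SequenceRecord]] = {}
    for gi, gene in enumerate(GENE_NAMES):
        tips, _ = _evolve_tree(
            tree, truth.n_codons, truth.syn_rate, truth.omega,
            int(np.random.default_rng([truth.seed, 100 + gi]).integers(2 ** 31)))
        gene_records[gene] = [
            SequenceRecord(id=f"{label}_{gene}", seq="".join(codons),
                           species=label)
            for label, codons in tips]

    # TE: vertical descent with captures for transfers and duplications
    captures: dict[str, list[tuple[int, float]]] = {}
    slot = 0
    event_slot: dict[int, int] = {}
    for ei, ev in enumerate(truth.htt_events):
        captures.setdefault(ev.donor, []).append((slot, ev.time_mya))
        event_slot[ei] = slot
        slot += 1
    dup_slot: dict[str, int] = {}
    if truth.copies_per_species > 1:
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            captures.setdefault(label, []).append((slot, truth.copy_age_mya))
            dup_slot[label] = slot
            slot += 1

    te_seed = int(np.random.default_rng([truth.seed, 200]).integers(2 ** 31))
    tips, captured = _evolve_tree(tree, truth.n_codons, truth.syn_rate,
                                  truth.omega, te_seed, captures=captures)

    te_records: list[SequenceRecord] = []
    for tip_idx, (label, codons) in enumerate(tips):
        te_records.append(SequenceRecord(id=f"{label}_00",
                                         seq="".join(codons), species=label))
        if truth.copies_per_species > 1:
            anc = captured[dup_slot[label]]
            dup_age = min(truth.copy_age_mya, terminal_start[label])
            for k in range(1, truth.copies_per_species):
                rng = np.random.default_rng([truth.seed, 300, tip_idx, k])
                seq = _evolve_segment(anc, dup_age, truth.syn_rate,
                                      truth.omega, rng)
                te_records.append(SequenceRecord(
                    id=f"{label}_{k:02d}", seq="".join(seq), species=label))

    truth_rows: list[dict] = []
    for ei, ev in enumerate(truth.htt_events):
        rng = np.random.default_rng([truth.seed, 400, ei])
        seq = _evolve_segment(captured[event_slot[ei]], ev.time_mya,
                              truth.syn_rate, truth.omega, rng)
        rec = SequenceRecord(id=f"{ev.recipient}_h{ev.copy_id}",
                             seq="".join(seq), species=ev.recipient)
        te_records.append(rec)
        truth_rows.append({
            "donor": ev.donor, "recipient": ev.recipient,
            "time_mya": ev.time_mya, "copy_id": ev.copy_id,
            "donor_copy": f"{ev.donor}_00", "recipient_copy": rec.id,
        })

    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return te_records, gene_records, newick, truth_rows


def true_te_tree(truth: SimTruth) -> str:
    """Newick string of the true genealogy of all simulated TE copies.

    The TE genealogy is the species tree with extra tips grafted onto
    terminal branches: a transferred copy diverges from the donor lineage at
    the transfer time, a duplicated copy at the duplication age. Branch
    lengths are in Myr, tip labels match the simulated copy ids.
    """
    tree = truth.species_tree
    ages = _node_ages(tree)
    # per-species insertions on the terminal branch: (age, tip label)
    insertions: dict[str, list[tuple[float, str]]] = {}
    for ev in truth.htt_events:
        insertions.setdefault(ev.donor, []).append(
            (ev.time_mya, f"{ev.recipient}_h{ev.copy_id}"))
    if truth.copies_per_species > 1:
        for leaf in tree.leaf_node_iter():
            sp = leaf.taxon.label
            dup_age = min(truth.copy_age_mya, ages[leaf.parent_node])
            for k in range(1, truth.copies_per_species):
                insertions.setdefault(sp, []).append((dup_age, f"{sp}_{k:02d}"))

    def terminal(sp: str, branch_start_age: float) -> str:
        ins = sorted(insertions.get(sp, []))
        cur, cur_age = f"{sp}_00", 0.0
        i = 0
        while i < len(ins):
            age = ins[i][0]
            sibs = [lab for a, lab in ins if a == age]
            i += len(sibs)
            tips = ",".join(f"{lab}:{age:.8g}" for lab in sibs)
            cur = f"({cur}:{age - cur_age:.8g},{tips})"
            cur_age = age
        return f"{cur}:{branch_start_age - cur_age:.8g}"

    def sub(node: dendropy.Node) -> str:
        if node.is_leaf():
            return terminal(node.taxon.label, ages[node.parent_node])
        inner = ",".join(sub(c) for c in node.child_nodes())
        if node.parent_node is None:
            return f"({inner});"
        return f"({inner}):{node.edge.length:.8g}"

    return sub(tree.seed_node)


def write_dataset(out_dir: str | Path, te_records, gene_records, newick,
                  truth_rows, te_tree_newick: str | None = None) -> None:
    """Write a simulated dataset: te.fa, one FASTA per gene, the species tree
    (tree.nwk), the true TE genealogy (te_tree.nwk, when given) and a truth
    TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(te_records, out / "te.fa")
    for gene, recs in gene_records.items():
        write_fasta(recs, out / f"{gene.lower()}.fa")
    (out / "tree.nwk").write_text(newick + "\n")
    if te_tree_newick is not None:
        (out / "te_tree.nwk").write_text(te_tree_newick + "\n")
    header = "donor\trecipient\ttime_mya\tcopy_id\tdonor_copy\trecipient_copy"
    lines = [header] + [
        f"{r['donor']}\t{r['recipient']}\t{r['time_mya']}\t{r['copy_id']}"
        f"\t{r['donor_copy']}\t{r['recipient_copy']}"
        for r in truth_rows]
    (out / "truth.tsv").write_text("\n".join(lines) + "\n")
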