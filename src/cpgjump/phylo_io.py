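"""Trees, codon alignments, and substitution-history files.

Newick parsing/writing is delegated to dendropy and FASTA I/O to Biopython;
this module adds the validation the simulator's contracts need (branch
lengths present and nonnegative, unique tip labels, sense codons only,
equal sequence lengths) and flattens the tree into preorder arrays that the
simulation and pruning code index directly.

Branch lengths are expected substitutions per codon site under the
site-independent (lam=1) reference model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STANDARD_CODE, STOP_CODONS
from .substitution_model import SequenceState


class PhyloFormatError(ValueError):
    """Malformed tree, alignment, or history input."""


@dataclass
class Phylogeny:
    """Rooted tree flattened to preorder arrays.

    Node 0 is the root; ``parent[i] < i`` for every non-root node, so a
    simple forward scan is a preorder traversal. Internal nodes without a
    label are auto-named ``n1, n2, ...`` in preorder, deterministically.
    """

    names: list[str]
    parent: np.ndarray          # parent index; -1 for the root
    lengths: np.ndarray         # branch length above each node; 0.0 for the root
    children: list[list[int]]

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise PhyloFormatError(f"could not parse Newick: {exc}") from exc
        return cls._from_dendropy(tree)

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        names, parent, lengths, children = [], [], [], []
        seen_tips: set[str] = set()
        auto = 0
        for i, nd in enumerate(nodes):
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if nd.is_leaf():
                if label is None:
                    raise PhyloFormatError(f"unlabeled tip (node {i})")
                if label in seen_tips:
                    raise PhyloFormatError(f"duplicate tip label {label!r}")
                seen_tips.add(label)
            elif label is None:
                auto += 1
                label = f"n{auto}"
            names.append(str(label))
            kids = [index[id(c)] for c in nd.child_nodes()]
            children.append(kids)
            if nd.parent_node is None:
                parent.append(-1)
                lengths.append(0.0)
                if len(kids) not in (2, 3):
                    raise PhyloFormatError(
                        f"root must have 2 or 3 children, found {len(kids)}"
                    )
            else:
                if nd.edge.length is None:
                    raise PhyloFormatError(f"missing branch length above node {label!r}")
                if not np.isfinite(nd.edge.length) or nd.edge.length < 0:
                    raise PhyloFormatError(
                        f"branch length above node {label!r} must be finite and >= 0"
                    )
                if kids and len(kids) != 2:
                    raise PhyloFormatError(
                        f"internal node {label!r} must be binary, found {len(kids)} children"
                    )
                parent.append(index[id(nd.parent_node)])
                lengths.append(float(nd.edge.length))
        return cls(names=names, parent=parent, lengths=lengths, children=children)

    # -- basic queries -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_tip(i)]

    @property
    def tip_labels(self) -> list[str]:
        return [self.names[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def total_length(self) -> float:
        return float(self.lengths[1:].sum())

    def branches(self) -> list[tuple[int, int, float]]:
        """(child, parent, length) triples in preorder."""
        return [
            (i, int(self.parent[i]), float(self.lengths[i]))
            for i in range(1, self.n_nodes)
        ]

    # -- writing / rerooting -------------------------------------------------

    def _to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [None] * self.n_nodes
        for i in range(self.n_nodes):
            nd = tree.seed_node if i == 0 else dendropy.Node()
            if self.is_tip(i):
                nd.taxon = taxa.require_taxon(label=self.names[i])
            else:
                nd.label = self.names[i]
            if i > 0:
                dnodes[self.parent[i]].add_child(nd)
                nd.edge.length = float(self.lengths[i])
            dnodes[i] = nd
        return tree

    def to_newick(self) -> str:
        tree = self._to_dendropy()
        out = tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=True,
            real_value_format_specifier=".12g",
        ).strip()
        return out + ("\n" if not out.endswith("\n") else "")

    def reroot_on_branch(self, child_name: str, offset: float) -> "Phylogeny":
        """New root inserted on the branch above `child_name` at `offset`
        from the parent end. Exposes the root-placement freedom a
        time-reversible process has."""
        try:
            child_idx = self.names.index(child_name)
        except ValueError:
            raise PhyloFormatError(f"no node named {child_name!r}") from None
        blen = float(self.lengths[child_idx])
        if not (0.0 <= offset <= blen):
            raise PhyloFormatError(f"offset {offset} outside branch length {blen}")
        tree = self._to_dendropy()
        target = None
        for nd in tree.preorder_node_iter():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label == child_name and nd.parent_node is not None:
                target = nd
                break
        tree.reroot_at_edge(target.edge, length1=offset, length2=blen - offset)
        # rerooting may leave the old root as a unifurcation; collapse it
        tree.suppress_unifurcations()
        for nd in tree.preorder_node_iter():
            if nd.taxon is None:
                nd.label = None  # drop stale internal names; renamed on rebuild
        return Phylogeny._from_dendropy(tree)


def parse_newick(text: str) -> Phylogeny:
    return Phylogeny.from_newick(text)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Ordered taxon -> codon sequence map; all sequences equal length."""

    sequences: dict[str, SequenceState]

    def __post_init__(self):
        if not self.sequences:
            raise PhyloFormatError("alignment must contain at least one sequence")
        lengths = {s.n_sites for s in self.sequences.values()}
        if len(lengths) != 1:
            raise PhyloFormatError(f"sequences have unequal codon lengths: {sorted(lengths)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_sites(self) -> int:
        return next(iter(self.sequences.values())).n_sites

    def codon_matrix(self, taxa_order=None) -> np.ndarray:
        """(n_taxa, n_sites) codon-index matrix."""
        order = self.taxa if taxa_order is None else list(taxa_order)
        return np.stack([self.sequences[t].codons for t in order])


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq.to_dna()), id=taxon, description="")
        for taxon, seq in alignment.sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_phylip(alignment: Alignment, path) -> None:
    """Sequential PHYLIP with relaxed (full-word) taxon names."""
    with open(path, "w") as fh:
        fh.write(f" {len(alignment.sequences)} {alignment.n_sites * 3}\n")
        for taxon, seq in alignment.sequences.items():
            fh.write(f"{taxon}  {seq.to_dna()}\n")


def _validate_codon_record(taxon: str, dna: str) -> SequenceState:
    if len(dna) % 3 != 0:
        raise PhyloFormatError(
            f"sequence for {taxon!r} has length {len(dna)}, not a multiple of 3"
        )
    codons = []
    for site, i in enumerate(range(0, len(dna), 3), start=1):
        codon = dna[i:i + 3].upper()
        if codon in STOP_CODONS:
            raise PhyloFormatError(f"stop codon {codon} in {taxon!r} at codon site {site}")
        if codon not in STANDARD_CODE.codon_to_index:
            raise PhyloFormatError(
                f"invalid codon {codon!r} in {taxon!r} at codon site {site}"
            )
        codons.append(STANDARD_CODE.codon_to_index[codon])
    return SequenceState(np.array(codons, dtype=np.int64))


def read_fasta(path) -> Alignment:
    if isinstance(path, io.IOBase):
        records = list(SeqIO.parse(path, "fasta"))
    else:
        with open(path) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise PhyloFormatError("empty FASTA file")
    sequences: dict[str, SequenceState] = {}
    for rec in records:
        if rec.id in sequences:
            raise PhyloFormatError(f"duplicate taxon {rec.id!r}")
        sequences[rec.id] = _validate_codon_record(rec.id, str(rec.seq))
    return Alignment(sequences)


# ---------------------------------------------------------------------------
# Substitution-history files
# ---------------------------------------------------------------------------

HISTORY_COLUMNS = (
    "branch",
    "event_index",
    "time",
    "site",
    "position",
    "from_codon",
    "to_codon",
    "class",
)


def write_history(history, path) -> None:
    """Write a simulation's full event record as TSV.

    One row per substitution event, ordered by branch (preorder) and by time
    within the branch; times are offsets from the parent end of the branch,
    printed with 12 significant digits; codon sites are 1-based. A FASTA
    side file ``<path>.nodes.fasta`` stores every node's sequence (ancestral
    states included).
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(HISTORY_COLUMNS) + "\n")
        for branch_name, events in history.branch_events.items():
            for k, ev in enumerate(events):
                fh.write(
                    f"{branch_name}\t{k}\t{ev.time:.12g}\t{ev.site + 1}\t"
                    f"{ev.position}\t{ev.from_codon}\t{ev.to_codon}\t{ev.klass}\n"
                )
    records = [
        SeqRecord(Seq(seq.to_dna()), id=name, description="")
        for name, seq in history.node_states.items()
    ]
    with open(str(path) + ".nodes.fasta", "w") as fh:
        SeqIO.write(records, fh, "fasta")
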