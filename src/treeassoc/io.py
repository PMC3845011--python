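"""Readers and writers for the package's on-disk formats.

Formats
-------
matrix-text
    Whitespace-separated haplotype panel: first row holds the L base-pair
    positions; each following row is ``<haplotype-id> <phenotype> <L alleles>``
    with alleles coded 0/1 and phenotype 1 for cases.
vcf-phased
    Phased biallelic VCF (read-only); each diploid sample contributes two
    haplotypes ``<sample>_1`` and ``<sample>_2``.  Phenotypes come from a
    side table keyed by haplotype id.
newick
    Rooted binary trees with branch lengths in coalescent time units; node
    time is the maximum path length to a descendant tip, so tips sit at 0.
results table
    Tab-separated per-focal-point summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .tree import RootedTree, TreeError

__all__ = [
    "HaplotypeDataset",
    "FocalSummary",
    "DataError",
    "read_haplotypes",
    "write_haplotypes",
    "read_phenotype_table",
    "read_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "write_results_table",
    "RESULT_COLUMNS",
]


class DataError(ValueError):
    """Raised when an input file violates a format or dataset invariant."""


# ----------------------------------------------------------------------
# haplotype panels
# ----------------------------------------------------------------------
@dataclass
class HaplotypeDataset:
    """Phased binary haplotype panel with per-haplotype phenotype labels.

    ``alleles`` is an ``H x L`` 0/1 matrix (one row per haplotype),
    ``positions`` holds strictly increasing 1-based base-pair coordinates,
    and ``phenotype`` codes cases as 1 (in a trio design, transmitted
    haplotypes) and controls as 0 (untransmitted).
    """

    alleles: np.ndarray
    positions: np.ndarray
    phenotype: np.ndarray
    haplotype_ids: tuple

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.phenotype = np.asarray(self.phenotype, dtype=np.uint8)
        self.haplotype_ids = tuple(str(x) for x in self.haplotype_ids)
        h, l = self.alleles.shape
        if h < 4:
            raise DataError(f"need at least 4 haplotypes, got {h}")
        if l < 1:
            raise DataError("need at least 1 SNP")
        if self.positions.shape != (l,):
            raise DataError("positions length must match number of SNPs")
        if np.any(np.diff(self.positions) <= 0):
            raise DataError("positions not ascending")
        if not np.isin(self.alleles, (0, 1)).all():
            raise DataError("alleles must be 0/1")
        if self.phenotype.shape != (h,):
            raise DataError("phenotype length must match number of haplotypes")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise DataError("phenotype must be 0/1")
        if len(set(self.haplotype_ids)) != h:
            raise DataError("haplotype ids must be unique")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def require_both_classes(self) -> None:
        """Association computations need at least one case and one control."""
        if self.phenotype.min() == self.phenotype.max():
            raise DataError("phenotype must contain both cases and controls")

    def window(self, start: int, stop: int) -> "HaplotypeDataset":
        """Dataset restricted to the SNP index range ``[start, stop)``."""
        if not (0 <= start < stop <= self.n_snps):
            raise DataError(f"invalid SNP window [{start}, {stop})")
        return HaplotypeDataset(
            self.alleles[:, start:stop],
            self.positions[start:stop],
            self.phenotype,
            self.haplotype_ids,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HaplotypeDataset)
            and self.haplotype_ids == other.haplotype_ids
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.phenotype, other.phenotype)
        )


def _read_matrix_text(path: str) -> HaplotypeDataset:
    with open(path) as fh:
        lines = [(i + 1, ln.strip()) for i, ln in enumerate(fh)]
    lines = [(no, ln) for no, ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise DataError(f"{path}: empty file")
    no, first = lines[0]
    try:
        positions = [int(tok) for tok in first.split()]
    except ValueError as exc:
        raise DataError(f"{path}, line {no}: positions row is not integer: {exc}") from None
    l = len(positions)
    ids, phen, rows = [], [], []
    for no, ln in lines[1:]:
        toks = ln.split()
        if len(toks) != l + 2:
            raise DataError(
                f"{path}, line {no}: expected id, phenotype and {l} alleles, got {len(toks)} fields"
            )
        ids.append(toks[0])
        if toks[1] not in ("0", "1"):
            raise DataError(f"{path}, line {no}: phenotype must be 0 or 1, got {toks[1]!r}")
        phen.append(int(toks[1]))
        try:
            row = [int(t) for t in toks[2:]]
        except ValueError:
            raise DataError(f"{path}, line {no}: alleles must be 0/1 integers") from None
        rows.append(row)
    return HaplotypeDataset(np.array(rows), positions, phen, ids)


def read_phenotype_table(path: str) -> dict:
    """Two-column whitespace table mapping haplotype id -> 0/1 phenotype."""
    out = {}
    with open(path) as fh:
        for no, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            toks = ln.split()
            if toks[0] == "id" and no == 1:
                continue  # optional header
            if len(toks) != 2 or toks[1] not in ("0", "1"):
                raise DataError(f"{path}, line {no}: expected '<id> <0|1>'")
            out[toks[0]] = int(toks[1])
    if not out:
        raise DataError(f"{path}: no phenotype entries")
    return out


def _read_vcf_phased(path: str, phenotype_path: str) -> HaplotypeDataset:
    import pysam

    phen_map = read_phenotype_table(phenotype_path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"{path}: cannot parse VCF: {exc}") from None
    samples = list(vcf.header.samples)
    if not samples:
        raise DataError(f"{path}: VCF has no samples")
    ids = [f"{s}_{k}" for s in samples for k in (1, 2)]
    positions, rows = [], []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise DataError(f"{path}: record at pos {rec.pos} is not biallelic")
        row = []
        for s in samples:
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                raise DataError(f"{path}: missing genotype at pos {rec.pos}, sample {s}")
            if not call.phased:
                raise DataError(f"{path}: unphased genotype at pos {rec.pos}, sample {s}")
            if any(a not in (0, 1) for a in gt):
                raise DataError(f"{path}: non-biallelic allele at pos {rec.pos}, sample {s}")
            row.extend(gt)
        positions.append(rec.pos)
        rows.append(row)
    if not rows:
        raise DataError(f"{path}: VCF has no variant records")
    missing = [i for i in ids if i not in phen_map]
    if missing:
        raise DataError(f"missing phenotype for haplotype id(s): {', '.join(missing[:5])}")
    phen = [phen_map[i] for i in ids]
    alleles = np.array(rows, dtype=np.uint8).T  # H x L
    order = np.argsort(np.asarray(positions))
    return HaplotypeDataset(alleles[:, order], np.asarray(positions)[order], phen, ids)


def read_haplotypes(
    path: str, format_name: str = "matrix-text", phenotype_path: Optional[str] = None
) -> HaplotypeDataset:
    """Read a phased case/control haplotype panel.

    ``format_name`` is ``"matrix-text"`` (phenotype inline) or
    ``"vcf-phased"`` (phenotype from the side table at ``phenotype_path``).
    """
    if format_name == "matrix-text":
        return _read_matrix_text(path)
    if format_name == "vcf-phased":
        if phenotype_path is None:
            raise DataError("vcf-phased input needs a phenotype side table")
        return _read_vcf_phased(path, phenotype_path)
    raise DataError(f"unknown haplotype format {format_name!r}")


def write_haplotypes(dataset: HaplotypeDataset, path: str) -> None:
    """Write a panel in matrix-text format."""
    with open(path, "w") as fh:
        fh.write(" ".join(str(int(p)) for p in dataset.positions) + "\n")
        for i, hid in enumerate(dataset.haplotype_ids):
            alleles = " ".join(str(int(a)) for a in dataset.alleles[i])
            fh.write(f"{hid} {int(dataset.phenotype[i])} {alleles}\n")


# ----------------------------------------------------------------------
# Newick trees
# ----------------------------------------------------------------------
def read_newick(text: str) -> RootedTree:
    """Parse one rooted binary ultrametric tree from a Newick string."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True, rooting="force-rooted"
        )
    except Exception as exc:
        raise DataError(f"cannot parse newick: {exc}") from None
    dnodes = list(dtree.preorder_node_iter())
    for node in dnodes:
        kids = node.child_nodes()
        if len(kids) not in (0, 2):
            raise DataError(f"non-binary node with {len(kids)} children; trees must be binary")
        if node.parent_node is not None:
            if node.edge.length is None:
                raise DataError("newick must supply branch lengths on every edge")
            if node.edge.length < 0:
                raise DataError("negative branch length")
    tips = [nd for nd in dnodes if nd.is_leaf()]
    n = len(tips)
    if n < 2:
        raise DataError("tree needs at least 2 tips")
    labels = []
    for nd in tips:
        lab = nd.taxon.label if nd.taxon is not None else None
        if not lab:
            raise DataError("every tip needs a label")
        labels.append(lab)
    if len(set(labels)) != n:
        raise DataError("tip labels must be unique")
    order = sorted(range(n), key=lambda i: labels[i])
    node_id = {id(tips[i]): rank for rank, i in enumerate(order)}
    next_id = n
    for nd in dtree.postorder_node_iter():
        if not nd.is_leaf():
            node_id[id(nd)] = next_id
            next_id += 1
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    # node time = max path length to a descendant tip
    depth = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = max(depth[id(c)] + c.edge.length for c in nd.child_nodes())
        v = node_id[id(nd)]
        time[v] = depth[id(nd)]
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None:
            parent[node_id[id(nd)]] = node_id[id(nd.parent_node)]
    try:
        return RootedTree(parent, time, [labels[i] for i in order])
    except TreeError as exc:
        raise DataError(f"invalid tree: {exc}") from None


def write_newick(tree: RootedTree) -> str:
    """Serialize a tree to Newick with branch lengths from node times."""
    ch = tree.children
    t = tree.time

    def render_with_lengths(v: int) -> str:
        if ch[v, 0] < 0:
            core = tree.tip_labels[v]
        else:
            a = render_with_lengths(ch[v, 0])
            b = render_with_lengths(ch[v, 1])
            core = f"({a},{b})"
        p = tree.parent[v]
        if p < 0:
            return core
        return f"{core}:{t[p] - t[v]:.12g}"

    return render_with_lengths(tree.root) + ";"


def read_newick_file(path: str) -> list:
    """Read one tree per non-empty line."""
    out = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln:
                out.append(read_newick(ln))
    if not out:
        raise DataError(f"{path}: no trees found")
    return out


def write_newick_file(trees: Sequence[RootedTree], path: str) -> None:
    with open(path, "w") as fh:
        for tr in trees:
            fh.write(write_newick(tr) + "\n")


# ----------------------------------------------------------------------
# results tables
# ----------------------------------------------------------------------
RESULT_COLUMNS = (
    "focal_bp",
    "n_snps_window",
    "mean_rho",
    "mean_theta",
    "median_latent_p",
    "q25",
    "q75",
    "q90",
    "n_tree_samples",
    "zero_replaced",
)


@dataclass
class FocalSummary:
    """Per-focal-point row of the region results table.

    ``m_prior`` (the number of coalescent prior draws M) sets the
    replacement value 1/M used when a latent p-value summary is exactly 0,
    so that the summary stays usable on a log scale; ``zero_replaced``
    records whether any replacement happened.
    """

    focal_bp: float
    n_snps_window: int
    mean_rho: float
    mean_theta: float
    median_latent_p: float
    q25: float
    q75: float
    q90: float
    n_tree_samples: int
    m_prior: int


def write_results_table(rows: Sequence[FocalSummary], path: str) -> pd.DataFrame:
    """Write per-focal-point summaries as TSV; returns the frame written.

    Latent p-value summaries equal to 0 are written as the 1/M replacement
    value with the ``zero_replaced`` flag set.
    """
    if len(rows) == 0:
        raise DataError("results table needs at least one row")
    recs = []
    for r in rows:
        vals = [r.focal_bp, r.n_snps_window, r.mean_rho, r.mean_theta,
                r.median_latent_p, r.q25, r.q75, r.q90, r.n_tree_samples]
        if any(not math.isfinite(float(v)) for v in vals):
            raise DataError(f"non-finite summary for focal point {r.focal_bp}")
        repl = 1.0 / r.m_prior
        flag = 0
        psum = []
        for p in (r.median_latent_p, r.q25, r.q75, r.q90):
            if p == 0.0:
                psum.append(repl)
                flag = 1
            else:
                psum.append(p)
        recs.append(
            dict(
                focal_bp=r.focal_bp,
                n_snps_window=r.n_snps_window,
                mean_rho=r.mean_rho,
                mean_theta=r.mean_theta,
                median_latent_p=psum[0],
                q25=psum[1],
                q75=psum[2],
                q90=psum[3],
                n_tree_samples=r.n_tree_samples,
                zero_replaced=flag,
            )
        )
    df = pd.DataFrame.from_records(recs, columns=list(RESULT_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
    return df
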