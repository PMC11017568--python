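"""Read, validate and harmonize phylogenies and echolocation trait tables.

The analyses in this package operate on an :class:`AlignedDataset`: a rooted
phylogeny whose tip set exactly matches a species-by-trait table, with the
continuous traits (body mass in g, peak frequency in kHz, bandwidth in kHz,
call duration in ms) stored on the log10 scale and a nasal/oral emission-type
factor derived from taxonomic family where not given explicitly.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import HarmonizationError, NewickError, TraitTableError

__all__ = [
    "PhyloTree",
    "TraitTable",
    "AlignedDataset",
    "read_newick",
    "read_trait_table",
    "classify_emission",
    "harmonize",
    "NASAL_FAMILIES",
    "ORAL_FAMILIES",
    "TRAIT_COLUMNS",
    "LOG_COLUMNS",
]

#: Families whose laryngeal calls are emitted through the nostrils.
NASAL_FAMILIES = frozenset(
    {
        "Hipposideridae",
        "Megadermatidae",
        "Nycteridae",
        "Phyllostomidae",
        "Rhinolophidae",
        "Rhinopomatidae",
    }
)

#: Families whose laryngeal calls are emitted through the mouth.
ORAL_FAMILIES = frozenset(
    {
        "Cistugidae",
        "Craseonycteridae",
        "Emballonuridae",
        "Furipteridae",
        "Miniopteridae",
        "Molossidae",
        "Mormoopidae",
        "Mystacinidae",
        "Myzopodidae",
        "Natalidae",
        "Noctilionidae",
        "Thyropteridae",
    }
)

#: Raw numeric trait columns expected in a trait table.
TRAIT_COLUMNS = {
    "mass_g": "body mass",
    "peak_khz": "peak frequency",
    "bandwidth_khz": "bandwidth",
    "duration_ms": "call duration",
}

#: Mapping raw column -> log10-transformed column used in analyses.
LOG_COLUMNS = {
    "mass_g": "log_mass",
    "peak_khz": "log_peak",
    "bandwidth_khz": "log_bandwidth",
    "duration_ms": "log_duration",
}


def _norm_name(name: str) -> str:
    """Normalize a species name: trim and map spaces to underscores.

    Matching is case-sensitive; only the space/underscore convention and
    surrounding whitespace are reconciled.
    """
    return "_".join(str(name).strip().split())


class PhyloTree:
    """A rooted phylogeny with branch lengths, backed by a dendropy tree.

    Invariants enforced on construction: a single root, unique tip labels,
    all branch lengths present and non-negative.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"malformed Newick string: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        t = self._tree
        if t.seed_node is None or len(t.leaf_nodes()) < 1:
            raise NewickError("tree has no tips")
        labels = []
        for leaf in t.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("tip without a label")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
        for nd in t.preorder_node_iter():
            if nd is t.seed_node:
                if nd.edge.length is None:
                    nd.edge.length = 0.0
                continue
            bl = nd.edge.length
            if bl is None:
                who = nd.taxon.label if nd.taxon else "internal node"
                raise NewickError(f"missing branch length on edge to {who!r}")
            if bl < 0:
                who = nd.taxon.label if nd.taxon else "internal node"
                raise NewickError(f"negative branch length {bl} on edge to {who!r}")
            if bl == 0.0 and nd.is_leaf():
                warnings.warn(
                    f"zero-length terminal branch at tip {nd.taxon.label!r}: "
                    "this tip has no independent variance",
                    stacklevel=3,
                )

    # -- basic queries -------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip (root stem edge excluded)."""
        depths: dict[str, float] = {}
        root = self._tree.seed_node
        node_depth = {root: 0.0}
        if root.is_leaf():
            return {root.taxon.label: 0.0}
        for nd in self._tree.preorder_node_iter():
            if nd is root:
                continue
            node_depth[nd] = node_depth[nd.parent_node] + nd.edge.length
            if nd.is_leaf():
                depths[nd.taxon.label] = node_depth[nd]
        return depths

    def height(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.asarray(list(self.tip_depths().values()))
        h = d.max()
        return bool(h == 0 or (d.max() - d.min()) <= rel_tol * h)

    def has_polytomies(self) -> bool:
        return any(
            len(nd.child_nodes()) > 2 for nd in self._tree.preorder_internal_node_iter()
        )

    # -- transforms ----------------------------------------------------

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def prune_to(self, keep: set[str] | list[str]) -> "PhyloTree":
        """Return a copy pruned to the given tip labels (unifurcations collapsed)."""
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise HarmonizationError(f"tips not in tree: {sorted(missing)}")
        t = self._tree.clone(depth=1)
        taxa = [leaf.taxon for leaf in t.leaf_node_iter() if leaf.taxon.label in keep]
        t.retain_taxa(taxa)
        t.seed_node.edge.length = 0.0
        return PhyloTree(t)

    def resolve_polytomies(self) -> "PhyloTree":
        """Resolve multifurcations into arbitrary zero-length bifurcations.

        Zero-length resolution leaves every Brownian-motion likelihood on
        the tree unchanged.
        """
        t = self._tree.clone(depth=1)
        t.resolve_polytomies()
        for nd in t.preorder_node_iter():
            if nd.edge.length is None:
                nd.edge.length = 0.0
        return PhyloTree(t)

    def as_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick", unquoted_underscores=True, suppress_rooting=True
            ).strip()
        )

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips>"


def read_newick(path) -> PhyloTree:
    """Parse a single-tree Newick file into a validated :class:`PhyloTree`."""
    with open(path) as fh:
        text = fh.read().strip()
    if not text:
        raise NewickError(f"empty Newick file: {path}")
    return PhyloTree.from_newick(text)


@dataclass
class TraitTable:
    """Raw species-by-trait table with validation flags.

    ``frame`` holds one row per species with the raw (untransformed) columns;
    ``problems`` lists rows that cannot enter a log10 analysis (non-positive
    or missing values), keyed by (species, column).
    """

    frame: pd.DataFrame
    problems: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["species", "column", "issue"])
    )

    @property
    def species(self) -> list[str]:
        return list(self.frame["species"])

    def __len__(self) -> int:
        return len(self.frame)


def read_trait_table(path) -> TraitTable:
    """Read a comma- or tab-delimited trait table.

    Required header columns: ``species``, ``mass_g``, ``peak_khz``,
    ``bandwidth_khz``, ``duration_ms``, ``family``; ``emission`` is optional
    (it can be derived from family via :func:`classify_emission`).
    Non-positive numeric values are flagged (log10 is undefined for them),
    not silently dropped; :func:`harmonize` applies the drop and reports it.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype={"species": str, "family": str})
    required = ["species", "family"] + list(TRAIT_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        names = ", ".join(f"{c} ({TRAIT_COLUMNS.get(c, c)})" for c in missing)
        raise TraitTableError(f"trait table missing required column(s): {names}")
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"].unique())
        raise TraitTableError(f"duplicate species rows: {dupes}")
    problems = []
    for col in TRAIT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_parse = df[col].notna() & vals.isna()
        for sp in df.loc[bad_parse, "species"]:
            raise TraitTableError(
                f"unparseable numeric value for {TRAIT_COLUMNS[col]} "
                f"({col}) in species {sp!r}"
            )
        df[col] = vals
        nonpos = vals.notna() & (vals <= 0)
        for sp in df.loc[nonpos, "species"]:
            problems.append((sp, col, "non-positive value (log10 undefined)"))
        missing_val = vals.isna()
        for sp in df.loc[missing_val, "species"]:
            problems.append((sp, col, "missing value"))
    if "emission" not in df.columns:
        df["emission"] = pd.NA
    prob = pd.DataFrame(problems, columns=["species", "column", "issue"])
    return TraitTable(frame=df, problems=prob)


def classify_emission(family_name: str) -> str:
    """Classify a bat family as a nasal or oral laryngeal echolocator.

    Returns ``"nasal"`` for the six nasal-emitting families, ``"oral"`` for
    the twelve oral-emitting families, and ``"unclassified"`` for anything
    else (e.g. the non-laryngeal Pteropodidae) — never a silent default.
    Trait tables may carry an explicit ``emission`` column, which takes
    precedence over this family-based rule during harmonization.
    """
    fam = str(family_name).strip()
    if fam in NASAL_FAMILIES:
        return "nasal"
    if fam in ORAL_FAMILIES:
        return "oral"
    return "unclassified"


@dataclass
class AlignedDataset:
    """Tree and traits reconciled for analysis.

    ``data`` is indexed by species (matching ``tree`` tips exactly) and holds
    the log10 trait columns plus ``family`` and ``emission`` factors; ``raw``
    retains the untransformed values for the same species.
    """

    tree: PhyloTree
    data: pd.DataFrame
    raw: pd.DataFrame | None = None
    report: pd.DataFrame | None = None

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    @classmethod
    def from_frames(cls, tree: PhyloTree, data: pd.DataFrame) -> "AlignedDataset":
        """Build directly from a tree and a species-indexed frame of
        already-transformed columns (used by the synthetic generators)."""
        if set(data.index) != set(tree.tip_labels):
            raise HarmonizationError("data index does not match tree tips")
        return cls(tree=tree, data=data.loc[tree.tip_labels].copy())

    def trait_matrix(self, columns: list[str]) -> np.ndarray:
        """Tip-ordered numeric matrix for the given columns."""
        return self.data.loc[self.tree.tip_labels, columns].to_numpy(dtype=float)


def harmonize(
    tree: PhyloTree,
    table: TraitTable,
    required_traits: list[str] | None = None,
) -> tuple[AlignedDataset, PhyloTree, pd.DataFrame]:
    """Intersect tree and table, drop unusable rows, log10-transform.

    ``required_traits`` lists the raw numeric columns that must be present
    and positive for a species to be kept (default: all four), plus
    optionally ``"emission"`` to require a classified emission type.
    Returns the aligned dataset, the pruned tree and a report frame with one
    row per input species: columns ``species``, ``action`` (kept/dropped)
    and ``reason``.
    """
    if required_traits is None:
        required_traits = list(TRAIT_COLUMNS)
    need_emission = "emission" in required_traits
    numeric_required = [c for c in required_traits if c in TRAIT_COLUMNS]
    unknown = [c for c in required_traits if c not in TRAIT_COLUMNS and c != "emission"]
    if unknown:
        raise TraitTableError(f"unknown required trait(s): {unknown}")

    df = table.frame.copy()
    df["species"] = df["species"].map(_norm_name)
    tip_map = {_norm_name(t): t for t in tree.tip_labels}

    # fill emission from family where absent
    emission = df["emission"].astype("object")
    derived = df["family"].map(classify_emission)
    emission = emission.where(emission.notna() & (emission != ""), derived)
    df["emission"] = emission

    rows = []
    keep_idx = []
    for idx, row in df.iterrows():
        sp = row["species"]
        if sp not in tip_map:
            rows.append((sp, "dropped", "not-in-tree"))
            continue
        reason = None
        for col in numeric_required:
            v = row[col]
            if pd.isna(v):
                reason = f"missing {TRAIT_COLUMNS[col]}"
                break
            if v <= 0:
                reason = f"non-positive {TRAIT_COLUMNS[col]}"
                break
        if reason is None and need_emission and row["emission"] not in ("nasal", "oral"):
            reason = "unclassified emission type"
        if reason is not None:
            rows.append((sp, "dropped", reason))
        else:
            rows.append((sp, "kept", ""))
            keep_idx.append(idx)

    report = pd.DataFrame(rows, columns=["species", "action", "reason"])
    kept = df.loc[keep_idx].copy()
    if kept.empty:
        raise HarmonizationError("no species shared between tree and trait table")

    kept_tips = [tip_map[sp] for sp in kept["species"]]
    pruned = tree.prune_to(kept_tips)
    # tree and table use one naming convention from here on
    for leaf in pruned.dendropy_tree.leaf_node_iter():
        leaf.taxon.label = _norm_name(leaf.taxon.label)
    if not pruned.is_ultrametric():
        warnings.warn("pruned tree is not ultrametric; GLS does not require it")

    out = pd.DataFrame(index=pd.Index(kept["species"], name="species"))
    for raw_col, log_col in LOG_COLUMNS.items():
        if raw_col in numeric_required:
            out[log_col] = np.log10(kept[raw_col].to_numpy(dtype=float))
        elif kept[raw_col].notna().all() and (kept[raw_col] > 0).all():
            out[log_col] = np.log10(kept[raw_col].to_numpy(dtype=float))
    out["family"] = kept["family"].to_numpy()
    out["emission"] = kept["emission"].to_numpy()
    out = out.loc[[_norm_name(t) for t in pruned.tip_labels]]

    raw = kept.set_index("species")
    dataset = AlignedDataset(tree=pruned, data=out, raw=raw, report=report)
    return dataset, pruned, report


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
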