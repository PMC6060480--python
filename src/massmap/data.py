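"""Data model and I/O: abundance tables, taxonomy lineages, trees, metadata.

All tabular formats are plain TSV (UTF-8).  Trees are newick.  Abundance
tables may hold raw counts or relative abundances; counts are converted to
per-sample relative abundance at load time and no zero replacement is
performed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIX = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """Malformed input file (negative counts, bad lineage string, ...)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a model invariant."""


def rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank)
    except ValueError:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}") from None


# ---------------------------------------------------------------------------
# Abundance matrix
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """Samples x taxa abundance matrix.

    ``values`` holds relative abundances after loading (rows of a freshly
    loaded matrix sum to one).  Sub-setting taxa keeps the original relative
    abundances, so rows of a filtered matrix may sum to less than one.
    """

    sample_ids: list
    taxon_ids: list
    values: np.ndarray
    is_counts: bool = False

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.taxon_ids = list(self.taxon_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("abundance values must be a 2-d matrix")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.taxon_ids):
            raise ValidationError("abundance matrix shape does not match identifiers")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != m:
            raise ValidationError("duplicate taxon identifiers")
        if np.any(self.values < 0):
            raise FormatError("negative abundance entry")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_table(cls, df: pd.DataFrame, normalize: bool = True) -> "AbundanceMatrix":
        values = df.to_numpy(dtype=float)
        if np.any(values < 0):
            raise FormatError("negative abundance entry")
        row_sums = values.sum(axis=1)
        if np.any(row_sums == 0):
            bad = [df.index[i] for i in np.flatnonzero(row_sums == 0)]
            raise ValidationError(f"all-zero sample(s): {bad}")
        is_counts = not np.allclose(row_sums, 1.0, atol=1e-6)
        if normalize:
            values = values / row_sums[:, None]
        return cls(list(df.index), list(df.columns), values, is_counts=is_counts)

    def subset_taxa(self, taxon_ids: Sequence) -> "AbundanceMatrix":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return AbundanceMatrix(
            self.sample_ids, list(taxon_ids), self.values[:, idx], is_counts=self.is_counts
        )

    def reorder_samples(self, sample_ids: Sequence) -> "AbundanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceMatrix(
            list(sample_ids), self.taxon_ids, self.values[idx], is_counts=self.is_counts
        )

    def column(self, taxon_id) -> np.ndarray:
        return self.values[:, self.taxon_ids.index(taxon_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


def load_abundance(
    path,
    orientation: str = "samples_as_rows",
    known_samples: Sequence | None = None,
) -> AbundanceMatrix:
    """Read a TSV abundance table and normalize rows to relative abundance.

    ``orientation`` is one of ``samples_as_rows``, ``taxa_as_rows`` or
    ``auto``; auto-detection matches the table's axes against
    ``known_samples`` (e.g. the identifiers of a metadata table).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric abundance body in {path}: {exc}") from None

    if orientation == "auto":
        if known_samples is None:
            raise ValidationError("orientation='auto' requires known_samples")
        known = set(map(str, known_samples))
        rows = len(known & set(map(str, df.index)))
        cols = len(known & set(map(str, df.columns)))
        orientation = "samples_as_rows" if rows >= cols else "taxa_as_rows"
    if orientation == "taxa_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    return AbundanceMatrix.from_table(df)


def write_abundance(ab: AbundanceMatrix, path) -> None:
    ab.to_dataframe().to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def parse_lineage(text: str, lineno: int | None = None) -> tuple:
    """Parse a Greengenes-style ``k__...; p__...; ...; s__...`` string.

    Missing or empty fields are recorded as unassigned ("").
    """
    where = f" (line {lineno})" if lineno is not None else ""
    labels = [""] * len(RANKS)
    parts = [p.strip() for p in text.split(";")]
    if len(parts) > len(RANKS):
        raise FormatError(f"lineage has more than {len(RANKS)} fields{where}: {text!r}")
    for i, part in enumerate(parts):
        if part == "":
            continue
        if not part.startswith(_PREFIX[i]):
            raise FormatError(
                f"malformed lineage field {part!r}{where}: expected prefix {_PREFIX[i]!r}"
            )
        labels[i] = part[len(_PREFIX[i]):].strip()
    return tuple(labels)


@dataclass
class TaxonomyMap:
    """Per-taxon lineage; induces the group partition at each rank."""

    lineage: dict

    def __post_init__(self):
        for tid, labels in self.lineage.items():
            if len(labels) != len(RANKS):
                raise ValidationError(f"lineage for {tid!r} must have {len(RANKS)} ranks")

    def label(self, taxon_id, rank: str) -> str:
        return self.lineage[taxon_id][rank_index(rank)]

    def is_assigned(self, taxon_id, rank: str) -> bool:
        return self.lineage[taxon_id][rank_index(rank)] != ""

    def group_key(self, taxon_id, rank: str) -> str:
        """Full lineage path down to ``rank`` (unique across parents)."""
        ri = rank_index(rank)
        labels = self.lineage[taxon_id][: ri + 1]
        return ";".join(p + l for p, l in zip(_PREFIX, labels))

    def partition(
        self,
        rank: str,
        taxa: Sequence | None = None,
        pool_unassigned: bool = False,
    ) -> dict:
        """Map group key -> list of taxon ids at ``rank``.

        Taxa unassigned at ``rank`` are excluded unless ``pool_unassigned``,
        in which case they form an unassigned group under their parent path.
        Group order follows first appearance in ``taxa``; member order is
        preserved.
        """
        if taxa is None:
            taxa = list(self.lineage)
        groups: dict = {}
        for t in taxa:
            if t not in self.lineage:
                raise ValidationError(f"taxon {t!r} has no lineage entry")
            if not self.is_assigned(t, rank) and not pool_unassigned:
                continue
            groups.setdefault(self.group_key(t, rank), []).append(t)
        return groups


def load_taxonomy(path) -> TaxonomyMap:
    """Read a two-column TSV of taxon id -> lineage string."""
    lineage: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tid, sep, lin = line.partition("\t")
            if not sep:
                raise FormatError(f"line {lineno}: expected two tab-separated columns")
            if lineno == 1 and "__" not in lin:
                continue  # header row
            lineage[tid] = parse_lineage(lin, lineno)
    if not lineage:
        raise FormatError(f"no taxonomy entries in {path}")
    return TaxonomyMap(lineage)


def filter_taxa(
    ab: AbundanceMatrix,
    tax: TaxonomyMap,
    min_rank: str = "family",
    min_prevalence: int = 3,
    min_mean_ra: float = 0.001,
) -> AbundanceMatrix:
    """Drop taxa unassigned at ``min_rank``, rare or low-abundance taxa.

    A taxon survives if it is assigned at ``min_rank``, has value > 0 in at
    least ``min_prevalence`` samples and mean relative abundance at least
    ``min_mean_ra``.  Surviving taxa keep their order; values are not
    re-normalized.
    """
    if min_prevalence < 0 or min_mean_ra < 0:
        raise ValidationError("filter thresholds must be nonnegative")
    prevalence = (ab.values > 0).sum(axis=0)
    mean_ra = ab.values.mean(axis=0)
    keep = []
    for j, t in enumerate(ab.taxon_ids):
        if t not in tax.lineage:
            raise ValidationError(f"taxon {t!r} has no lineage entry")
        if not tax.is_assigned(t, min_rank):
            continue
        if prevalence[j] < min_prevalence or mean_ra[j] < min_mean_ra:
            continue
        keep.append(t)
    if not keep:
        raise ValidationError("all taxa removed by filtering")
    return ab.subset_taxa(keep)


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; leaf labels are taxon ids."""

    tree: TreeNode

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(TreeNode.read(io.StringIO(newick)))

    @classmethod
    def read(cls, path) -> "PhyloTree":
        return cls(TreeNode.read(str(path)))

    def write(self, path) -> None:
        self.tree.write(str(path))

    @property
    def taxon_ids(self) -> list:
        return [t.name for t in self.tree.tips()]

    def _check_taxa(self, taxa: Sequence) -> None:
        missing = set(taxa) - set(self.taxon_ids)
        if missing:
            raise ValidationError(f"taxa missing from tree: {sorted(missing)}")

    def cophenetic(self, taxa: Sequence | None = None) -> np.ndarray:
        """Tip-to-tip patristic distance matrix, ordered as ``taxa``."""
        if taxa is None:
            taxa = self.taxon_ids
        self._check_taxa(taxa)
        dm = self.tree.tip_tip_distances()
        idx = [dm.index(t) for t in taxa]
        return dm.data[np.ix_(idx, idx)]

    def shear(self, taxa: Sequence) -> "PhyloTree":
        self._check_taxa(taxa)
        return PhyloTree(self.tree.shear(list(taxa)))

    def branch_matrix(self, taxa: Sequence) -> tuple:
        """Branch lengths and leaf incidence for the subtree spanning ``taxa``.

        Returns ``(lengths, incidence)`` where ``lengths`` is (E,) and
        ``incidence`` is an (E, M) 0/1 matrix marking which of the M taxa
        descend from each branch (one branch per non-root node).
        """
        self._check_taxa(taxa)
        sub = self.tree.shear(list(taxa)) if set(taxa) != set(self.taxon_ids) else self.tree.copy()
        col = {t: i for i, t in enumerate(taxa)}
        lengths, rows = [], []
        for node in sub.postorder(include_self=False):
            if node.is_tip():
                mask = np.zeros(len(taxa))
                mask[col[node.name]] = 1.0
            else:
                mask = np.sum([c._mm_mask for c in node.children], axis=0)
            node._mm_mask = mask
            lengths.append(node.length or 0.0)
            rows.append(mask)
        for node in sub.postorder(include_self=False):
            del node._mm_mask
        if not rows:  # single-tip subtree collapses to a root with no edges
            return np.empty(0), np.empty((0, len(taxa)))
        return np.asarray(lengths), np.asarray(rows)


def load_tree(path) -> PhyloTree:
    return PhyloTree.read(path)


# ---------------------------------------------------------------------------
# Traits / metadata
# ---------------------------------------------------------------------------


@dataclass
class TraitData:
    """Outcome and covariates for one analysis."""

    y: np.ndarray
    X: np.ndarray
    trait_type: str

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.size == 0:
            self.X = self.X.reshape(len(self.y), 0)
        if self.X.shape[0] != len(self.y):
            raise ValidationError("covariate rows do not match outcome length")
        if self.trait_type not in ("binary", "continuous"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            classes = set(np.unique(self.y))
            if not classes <= {0.0, 1.0}:
                raise ValidationError("binary trait must be coded 0/1")
            if len(classes) < 2:
                raise ValidationError("binary trait must have both classes present")
        design = np.column_stack([np.ones(len(self.y)), self.X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError("covariates are collinear with the intercept")

    @property
    def n(self) -> int:
        return len(self.y)


def load_metadata(
    path,
    trait: str,
    covariates: Sequence[str] = (),
    trait_type: str = "binary",
) -> tuple:
    """Read a metadata TSV; returns ``(TraitData, sample_ids)``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [trait, *covariates]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing column(s): {missing}")
    sub = df[cols]
    if sub.isna().any().any():
        raise ValidationError("missing values in trait/covariate columns")
    trait_data = TraitData(
        y=sub[trait].to_numpy(dtype=float),
        X=sub[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(sub), 0)),
        trait_type=trait_type,
    )
    return trait_data, list(df.index)


def align_samples(ab: AbundanceMatrix, trait: TraitData, sample_ids: Sequence):
    """Align abundance rows with metadata sample order (intersection)."""
    common = [s for s in sample_ids if s in set(ab.sample_ids)]
    if not common:
        raise ValidationError("no overlap between abundance and metadata sample ids")
    keep = [i for i, s in enumerate(sample_ids) if s in set(ab.sample_ids)]
    trait_sub = TraitData(trait.y[keep], trait.X[keep], trait.trait_type)
    return ab.reorder_samples(common), trait_sub, common
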