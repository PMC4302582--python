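"""Top-level model object for a congruence analysis.

:class:`CongruenceAnalysis` is built from a set of gene trees plus a
reference (concatenation) tree — optionally with the families' alignments —
or directly from a :class:`~congruity.simulate.SimConfig`. Its :meth:`fit`
runs the whole statistical battery and returns a
:class:`CongruenceResults` carrying the tables: per-node scores, the split
pool and its analytic bounds, per-family covariates, length bins with
distinct-split counts, correlations, a depth-group comparison of node
scores, and the split depth/frequency distribution. ``summary()`` renders a
text report; ``save()`` writes the TSV/newick/manifest report directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .congruence import (
    annotate_reference_tree,
    node_score,
    split_depth_distribution,
)
from .infer import bootstrap_support, nj_tree
from .io import (
    Alignment,
    ValidationError,
    check_common_taxa,
    write_newick,
)
from .simulate import SimConfig, SimulatedDataset, generate_dataset
from .splits import TaxonSet, build_split_pool
from .stats import (
    GeneFamily,
    bin_families_by_length,
    compare_node_score_groups,
    pearson,
)

__all__ = ["CongruenceAnalysis", "CongruenceResults"]

SHALLOW_MAX_TIP_DISTANCE = 2.0
DEEP_MIN_TIP_DISTANCE = 4.0


def concatenate_alignments(alignments: list[Alignment]) -> Alignment:
    """Column-wise concatenation (supermatrix) over a shared taxon set."""
    if not alignments:
        raise ValidationError("no alignments to concatenate")
    ids = sorted(alignments[0].ids)
    for aln in alignments:
        if sorted(aln.ids) != ids:
            raise ValidationError("alignments cover different taxon sets")
    seqs = ["".join(a.sequence(tid) for a in alignments) for tid in ids]
    return Alignment(ids=ids, seqs=seqs)


class CongruenceAnalysis:
    """Congruence of a gene-tree set with a reference tree.

    Parameters
    ----------
    families
        One :class:`~congruity.stats.GeneFamily` per gene; each must carry
        a tree, alignments are optional.
    reference_tree
        The concatenation (or species) tree the gene trees are scored
        against.
    """

    def __init__(self, families: list[GeneFamily], reference_tree: dendropy.Tree):
        if not families:
            raise ValidationError("no gene families supplied")
        for fam in families:
            if fam.tree is None:
                raise ValidationError(f"family {fam.family_id} has no tree")
        self.families = families
        self.reference_tree = reference_tree
        self.taxon_labels = check_common_taxa(
            [f.tree for f in families], reference_tree
        )
        self.taxon_set = TaxonSet(self.taxon_labels)
        self.dataset: SimulatedDataset | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_trees(
        cls,
        gene_trees,
        reference_tree: dendropy.Tree,
        alignments: list[Alignment] | None = None,
        family_ids: list[str] | None = None,
    ) -> "CongruenceAnalysis":
        gene_trees = list(gene_trees)
        if family_ids is None:
            family_ids = [f"fam{i:03d}" for i in range(1, len(gene_trees) + 1)]
        if alignments is None:
            alignments = [None] * len(gene_trees)
        if len(alignments) != len(gene_trees):
            raise ValidationError("alignments and gene trees differ in number")
        families = [
            GeneFamily(family_id=fid, alignment=aln, tree=t).compute_covariates()
            for fid, aln, t in zip(family_ids, alignments, gene_trees)
        ]
        return cls(families, reference_tree)

    @classmethod
    def from_simulation(
        cls,
        config: SimConfig,
        infer_trees: bool = False,
        bootstrap_replicates: int = 0,
        species_tree: dendropy.Tree | None = None,
    ) -> "CongruenceAnalysis":
        """Generate a synthetic dataset and wrap it for analysis.

        With ``infer_trees`` the gene trees are re-inferred from the evolved
        alignments by neighbor joining and the reference tree is the NJ tree
        of the concatenated alignment — the closed-loop emulation of the
        real pipeline. Otherwise the true (SPR-perturbed) gene trees are
        scored against the true species tree; alignments are then only
        evolved if bootstrap supports are requested.
        """
        evolve = infer_trees or bootstrap_replicates > 0
        dataset = generate_dataset(config, species_tree=species_tree, evolve=evolve)
        if infer_trees:
            for fam in dataset.families:
                fam.tree = nj_tree(fam.alignment)
            reference = nj_tree(concatenate_alignments(dataset.alignments))
        else:
            reference = dataset.species_tree
        obj = cls(dataset.families, reference)
        obj.dataset = dataset
        if bootstrap_replicates > 0:
            obj.attach_bootstrap(bootstrap_replicates, seed=config.seed)
        return obj

    # -- optional bootstrap stage ------------------------------------------

    def attach_bootstrap(
        self,
        replicates: int,
        seed: int | None = None,
        include_reference: bool = True,
    ) -> None:
        """Annotate each family tree (and the reference) with NJ bootstrap
        proportions computed from its alignment."""
        ss = np.random.SeedSequence(seed)
        seeds = ss.spawn(len(self.families) + 1)
        for fam, child in zip(self.families, seeds[:-1]):
            if fam.alignment is None:
                continue
            bootstrap_support(
                fam.alignment,
                replicates=replicates,
                seed=int(child.generate_state(1)[0] % 2**31),
                point_tree=fam.tree,
            )
            fam.compute_covariates()
        if include_reference:
            alignments = [f.alignment for f in self.families if f.alignment]
            if alignments:
                bootstrap_support(
                    concatenate_alignments(alignments),
                    replicates=replicates,
                    seed=int(seeds[-1].generate_state(1)[0] % 2**31),
                    point_tree=self.reference_tree,
                )

    # -- fitting ------------------------------------------------------------

    def fit(self, bin_size: int = 5, alpha: float = 0.05) -> "CongruenceResults":
        gene_trees = [f.tree for f in self.families]
        pool = build_split_pool(gene_trees, self.taxon_set)
        scores = node_score(self.reference_tree, gene_trees, self.taxon_set)
        depth_table = split_depth_distribution(gene_trees, self.taxon_set)
        annotated = annotate_reference_tree(self.reference_tree, scores)

        families_df = pd.DataFrame(
            [
                {
                    "family_id": f.family_id,
                    "mean_sequence_length": f.mean_sequence_length,
                    "alignment_length": f.alignment_length,
                    "pairwise_identity": f.pairwise_identity,
                    "mean_support": f.mean_support,
                }
                for f in self.families
            ]
        )

        with_covariates = [
            f for f in self.families if f.mean_sequence_length is not None
        ]
        bins_df = None
        if len(with_covariates) >= 2 * bin_size:
            bins = bin_families_by_length(with_covariates, bin_size=bin_size)
            bins_df = pd.DataFrame(
                [
                    {
                        "bin": b.index,
                        "n_families": b.size,
                        "mean_sequence_length": b.mean_sequence_length,
                        "distinct_splits": b.distinct_splits,
                        "mean_support": b.mean_support,
                    }
                    for b in bins
                ]
            )

        correlations = self._correlations(families_df, bins_df)
        depth_comparison = self._depth_comparison(scores, alpha)

        manifest = {
            "package": "congruity",
            "version": __version__,
            "n_taxa": len(self.taxon_set),
            "n_families": len(self.families),
            "bin_size": bin_size,
            "alpha": alpha,
            "config": self.dataset.config.to_dict() if self.dataset else None,
        }
        return CongruenceResults(
            model=self,
            node_scores=scores,
            split_pool=pool,
            split_depth=depth_table,
            families=families_df,
            bins=bins_df,
            correlations=correlations,
            depth_comparison=depth_comparison,
            annotated_tree=annotated,
            manifest=manifest,
        )

    def _correlations(self, families_df, bins_df):
        rows = []

        def corr(tag, x, y):
            x = np.asarray(x, dtype=float)
            y = np.asarray(y, dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                return
            r, p = pearson(x[ok], y[ok])
            rows.append({"pair": tag, "n": int(ok.sum()), "r": r, "P": p})

        if bins_df is not None:
            corr(
                "bin_mean_sequence_length~distinct_splits",
                bins_df["mean_sequence_length"],
                bins_df["distinct_splits"],
            )
            if bins_df["mean_support"].notna().any():
                corr(
                    "bin_mean_sequence_length~mean_support",
                    bins_df["mean_sequence_length"],
                    bins_df["mean_support"],
                )
        f = families_df
        for x_col in ("mean_sequence_length", "alignment_length", "pairwise_identity"):
            if f[x_col].notna().any() and f["mean_support"].notna().any():
                corr(f"{x_col}~mean_support", f[x_col], f["mean_support"])
        if (
            f["mean_sequence_length"].notna().any()
            and f["pairwise_identity"].notna().any()
        ):
            corr(
                "mean_sequence_length~pairwise_identity",
                f["mean_sequence_length"],
                f["pairwise_identity"],
            )
        if not rows:
            return None
        return pd.DataFrame(rows, columns=["pair", "n", "r", "P"])

    def _depth_comparison(self, scores, alpha):
        shallow = scores.loc[
            scores["tip_distance"] <= SHALLOW_MAX_TIP_DISTANCE, "score_fraction"
        ]
        deep = scores.loc[
            scores["tip_distance"] >= DEEP_MIN_TIP_DISTANCE, "score_fraction"
        ]
        mid = scores.loc[
            (scores["tip_distance"] > SHALLOW_MAX_TIP_DISTANCE)
            & (scores["tip_distance"] < DEEP_MIN_TIP_DISTANCE),
            "score_fraction",
        ]
        groups, labels = [], []
        for name, g in (("shallow", shallow), ("intermediate", mid), ("deep", deep)):
            if len(g) >= 2:
                groups.append(g.to_numpy())
                labels.append(name)
        if len(groups) < 2:
            return None
        if np.ptp(np.concatenate(groups)) == 0:
            return None  # degenerate: every node has the same score
        return compare_node_score_groups(groups, alpha=alpha, labels=labels)


@dataclass
class CongruenceResults:
    """Fitted congruence analysis: tables, annotated tree, manifest."""

    model: CongruenceAnalysis
    node_scores: pd.DataFrame
    split_pool: object
    split_depth: pd.DataFrame
    families: pd.DataFrame
    bins: pd.DataFrame | None
    correlations: pd.DataFrame | None
    depth_comparison: pd.DataFrame | None
    annotated_tree: dendropy.Tree
    manifest: dict = field(default_factory=dict)

    @property
    def mean_node_score_fraction(self) -> float:
        return float(self.node_scores["score_fraction"].mean())

    def summary(self) -> str:
        pool = self.split_pool
        lines = [
            "Congruence analysis",
            "===================",
            f"taxa:            {self.manifest['n_taxa']}",
            f"gene trees:      {self.manifest['n_families']}",
            f"internal nodes:  {len(self.node_scores)}",
            "",
            f"split pool size: {pool.size}"
            f"  (bounds: {pool.min_possible} total congruence,"
            f" {pool.max_possible} total incongruence)",
            f"mean node score: {self.node_scores['score_count'].mean():.2f}"
            f" of {self.manifest['n_families']}"
            f" ({100 * self.mean_node_score_fraction:.1f}%"
            f" +/- {100 * self.node_scores['score_fraction'].std():.1f}%)",
        ]
        if self.node_scores["support"].notna().any():
            lines.append(
                f"mean reference BP: {self.node_scores['support'].mean():.1f}"
            )
        if self.correlations is not None:
            lines.append("")
            lines.append("correlations (Pearson):")
            for _, row in self.correlations.iterrows():
                lines.append(
                    f"  {row['pair']}: r = {row['r']:+.3f}"
                    f" (P = {row['P']:.3g}, n = {row['n']})"
                )
        if self.depth_comparison is not None:
            anova = self.depth_comparison.attrs.get("anova", {})
            lines.append("")
            lines.append(
                "node scores by depth class (ANOVA"
                f" F = {anova.get('F', float('nan')):.2f},"
                f" P = {anova.get('P', float('nan')):.3g}):"
            )
            for _, row in self.depth_comparison.iterrows():
                flag = "*" if row["significant"] else " "
                lines.append(
                    f"  {row['group_a']} vs {row['group_b']}:"
                    f" diff = {row['mean_diff']:+.3f},"
                    f" P = {row['p_adj']:.3g} {flag}"
                )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the report directory: TSV tables, annotated newick,
        manifest JSON. Byte-identical for identical inputs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.6g"
        self.node_scores.to_csv(
            outdir / "node_scores.tsv", sep="\t", index=False, float_format=fmt
        )
        self.split_pool.to_frame().to_csv(
            outdir / "split_pool.tsv", sep="\t", index=False, float_format=fmt
        )
        self.split_depth.to_csv(
            outdir / "split_depth.tsv", sep="\t", index=False, float_format=fmt
        )
        self.families.to_csv(
            outdir / "families.tsv", sep="\t", index=False, float_format=fmt
        )
        skipped = []
        for name, table in (
            ("bins", self.bins),
            ("correlations", self.correlations),
            ("depth_comparison", self.depth_comparison),
        ):
            if table is None:
                skipped.append(name)
            else:
                table.to_csv(
                    outdir / f"{name}.tsv", sep="\t", index=False, float_format=fmt
                )
        with open(outdir / "annotated_reference.nwk", "w") as fh:
            fh.write(
                write_newick(self.annotated_tree, include_annotations=True) + "\n"
            )
        manifest = dict(self.manifest)
        manifest["split_pool_size"] = self.split_pool.size
        manifest["skipped_sections"] = skipped
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
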