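"""Differential exon usage between two conditions from replicate count tables.

The question asked per exon is whether the *fraction* of its gene's reads
falling on that exon differs between control and knockdown, independently of
overall gene expression. Replicate counts are summed per condition and each
exon is tested with a two-sided conditional exact (Fisher) test on the 2x2
table [exon, gene-rest] x [control, knockdown]; Benjamini-Hochberg controls
the FDR across tested exons. The effect size is

    log2_usage_change = log2((exon_kd+0.5)/(rest_kd+0.5))
                      - log2((exon_ctl+0.5)/(rest_ctl+0.5))

so positive values mean the exon takes a larger share of its gene in the
knockdown ("exclusive" exons in the MeCP2 literature: more excluded in
normal cells); significant negative exons are "inclusive".

This is a deliberate simplification of an exon-level negative-binomial GLM
(the DEXSeq approach): because counts are multinomial within a gene
conditional on the gene total, the exon-versus-rest split is binomial given
its margins and the conditional exact test is valid regardless of gene-level
overdispersion, as long as within-gene usage proportions are stable across
replicates. Replicate-to-replicate variation in the *proportions* themselves
is not modelled; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import ExonRecord

__all__ = [
    "ExonUsageModel",
    "ExonUsageResults",
    "usage_test",
    "classify_exons",
    "gene_level_summary",
    "ConfigurationError",
    "ReconciliationError",
]

CONDITIONS = ("control", "knockdown")


class ConfigurationError(ValueError):
    """Design/configuration problem (missing condition, empty inputs)."""


class ReconciliationError(KeyError):
    """Result exon_ids cannot be matched to the annotation."""


class ExonUsageModel:
    """Exon-usage model for a two-condition replicate count table.

    Parameters
    ----------
    counts
        DataFrame indexed by exon_id, one column per sample, non-negative
        integer read counts.
    design
        Mapping sample_id -> condition; conditions must be exactly
        ``control`` and ``knockdown`` (both present).
    annotation
        Optional list of :class:`ExonRecord` providing the exon -> gene
        linkage. When omitted, gene_ids are parsed from exon_ids of the form
        ``gene:Ennn``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        design: Mapping[str, str],
        annotation: Sequence[ExonRecord] | None = None,
    ):
        missing = [s for s in counts.columns if s not in design]
        if missing:
            raise ConfigurationError(f"samples missing from design: {missing}")
        conds = set(design[s] for s in counts.columns)
        if not set(CONDITIONS) <= conds:
            raise ConfigurationError(
                f"design must contain both conditions {CONDITIONS}, got {sorted(conds)}"
            )
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.design = dict(design)
        self.annotation = list(annotation) if annotation is not None else None
        if self.annotation is not None:
            gene_of = {ex.exon_id: ex.gene_id for ex in self.annotation}
            unknown = [e for e in counts.index if e not in gene_of]
            if unknown:
                raise ReconciliationError(
                    f"count table exon_ids absent from annotation: {unknown[:5]}"
                    + ("..." if len(unknown) > 5 else "")
                )
            self.gene_ids = pd.Series([gene_of[e] for e in counts.index], index=counts.index)
        else:
            self.gene_ids = pd.Series(
                [e.rsplit(":", 1)[0] for e in counts.index], index=counts.index
            )

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        design_path: str | Path,
        annotation: Sequence[ExonRecord] | None = None,
    ) -> "ExonUsageModel":
        """Build from a counts TSV (first column exon_id) and design TSV (sample_id, condition)."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design_df = pd.read_csv(design_path, sep="\t")
        design = dict(zip(design_df.iloc[:, 0], design_df.iloc[:, 1]))
        return cls(counts, design, annotation)

    def fit(
        self,
        alpha: float = 0.05,
        min_gene_count: int = 20,
        adjust: bool = True,
    ) -> "ExonUsageResults":
        """Test every exon and classify as up / down / unchanged / untested.

        Exons of single-bin genes (empty gene-rest) and exons of genes with
        summed counts below ``min_gene_count`` in either condition are
        reported ``untested``. Classification threshold is
        ``p_adjust <= alpha`` (raw p when ``adjust=False``).
        """
        if not (0 < alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")
        ctl_cols = [s for s in self.counts.columns if self.design[s] == "control"]
        kd_cols = [s for s in self.counts.columns if self.design[s] == "knockdown"]
        exon_ctl = self.counts[ctl_cols].sum(axis=1)
        exon_kd = self.counts[kd_cols].sum(axis=1)
        gene_ctl = exon_ctl.groupby(self.gene_ids).transform("sum")
        gene_kd = exon_kd.groupby(self.gene_ids).transform("sum")
        rest_ctl = gene_ctl - exon_ctl
        rest_kd = gene_kd - exon_kd
        n_bins = self.counts.groupby(self.gene_ids).size().reindex(self.gene_ids.values)
        n_bins.index = self.counts.index

        testable = (
            (n_bins > 1)
            & (gene_ctl >= min_gene_count)
            & (gene_kd >= min_gene_count)
        )

        res = pd.DataFrame(
            {
                "exon_id": self.counts.index,
                "gene_id": self.gene_ids.values,
                "exon_control": exon_ctl.values,
                "rest_control": rest_ctl.values,
                "exon_knockdown": exon_kd.values,
                "rest_knockdown": rest_kd.values,
            }
        ).set_index("exon_id")

        lfc = np.log2((exon_kd + 0.5) / (rest_kd + 0.5)) - np.log2(
            (exon_ctl + 0.5) / (rest_ctl + 0.5)
        )
        res["log2_usage_change"] = lfc.values

        stat = np.full(len(res), np.nan)
        pval = np.full(len(res), np.nan)
        idx = np.flatnonzero(testable.values)
        tab = res[["exon_control", "rest_control", "exon_knockdown", "rest_knockdown"]].to_numpy()
        for i in idx:
            a, b, c, d = tab[i]
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            stat[i] = odds
            pval[i] = p
        res["stat"] = stat
        res["p_value"] = pval

        padj = np.full(len(res), np.nan)
        if len(idx):
            padj[idx] = multipletests(pval[idx], method="fdr_bh")[1]
        res["p_adjust"] = padj

        crit = res["p_adjust"] if adjust else res["p_value"]
        cls = np.where(
            ~testable.values,
            "untested",
            np.where(
                (crit.values <= alpha) & (res["log2_usage_change"].values > 0),
                "up",
                np.where(
                    (crit.values <= alpha) & (res["log2_usage_change"].values < 0),
                    "down",
                    "unchanged",
                ),
            ),
        )
        res["usage_class"] = cls
        return ExonUsageResults(res, alpha=alpha, adjust=adjust, model=self)


@dataclass
class ExonUsageResults:
    """Per-exon usage test results with classification helpers."""

    table: pd.DataFrame
    alpha: float
    adjust: bool
    model: ExonUsageModel | None = None

    @property
    def n_up(self) -> int:
        return int((self.table["usage_class"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["usage_class"] == "down").sum())

    @property
    def n_tested(self) -> int:
        return int((self.table["usage_class"] != "untested").sum())

    def summary(self) -> str:
        t = self.table
        lines = [
            "Differential exon usage (conditional exact test, BH-adjusted)"
            if self.adjust
            else "Differential exon usage (conditional exact test, raw p)",
            f"  exons: {len(t)} total, {self.n_tested} tested, "
            f"{len(t) - self.n_tested} untested",
            f"  significant at alpha={self.alpha}: {self.n_up} up (exclusive), "
            f"{self.n_down} down (inclusive)",
        ]
        return "\n".join(lines)

    def classify_exons(self, annotation: Sequence[ExonRecord]) -> list[ExonRecord]:
        """Return the annotation with ``usage_class`` filled from these results.

        Exons absent from the results stay ``untested``. A result exon_id
        missing from the annotation raises :class:`ReconciliationError`.
        """
        known = {ex.exon_id for ex in annotation}
        orphans = [e for e in self.table.index if e not in known]
        if orphans:
            raise ReconciliationError(
                f"result exon_ids absent from annotation: {orphans}"
            )
        cls_of = self.table["usage_class"].to_dict()
        return [
            replace(ex, usage_class=cls_of.get(ex.exon_id, "untested"))
            for ex in annotation
        ]

    def gene_level_summary(
        self, gene_expression: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        """Per-gene tallies of significant exons, optionally joined to gene-level DE.

        ``gene_expression`` may carry a ``log2_fold_change`` column indexed by
        gene_id; its sign becomes ``gene_direction``. Genes without any
        significant exon are omitted.
        """
        sig = self.table[self.table["usage_class"].isin(["up", "down"])]
        if sig.empty:
            return pd.DataFrame(
                columns=["n_up_exons", "n_down_exons", "gene_direction"]
            ).rename_axis("gene_id")
        tally = (
            sig.groupby("gene_id")["usage_class"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["up", "down"], fill_value=0)
            .rename(columns={"up": "n_up_exons", "down": "n_down_exons"})
        )
        tally["gene_direction"] = "unknown"
        if gene_expression is not None and "log2_fold_change" in gene_expression:
            lfc = gene_expression["log2_fold_change"]
            common = tally.index.intersection(lfc.index)
            tally.loc[common, "gene_direction"] = np.where(
                lfc.loc[common] > 0, "up", np.where(lfc.loc[common] < 0, "down", "flat")
            )
        return tally

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "gene_id",
            "stat",
            "p_value",
            "p_adjust",
            "log2_usage_change",
            "usage_class",
        ]
        self.table[cols].to_csv(path, sep="\t")


def usage_test(
    counts: pd.DataFrame,
    annotation: Sequence[ExonRecord],
    design: Mapping[str, str],
    alpha: float = 0.05,
    min_gene_count: int = 20,
    adjust: bool = True,
) -> ExonUsageResults:
    """Functional wrapper: fit an :class:`ExonUsageModel` in one call."""
    return ExonUsageModel(counts, design, annotation).fit(
        alpha=alpha, min_gene_count=min_gene_count, adjust=adjust
    )


def classify_exons(
    results: ExonUsageResults, annotation: Sequence[ExonRecord]
) -> list[ExonRecord]:
    return results.classify_exons(annotation)


def gene_level_summary(
    results: ExonUsageResults, gene_expression: pd.DataFrame | None = None
) -> pd.DataFrame:
    return results.gene_level_summary(gene_expression)
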