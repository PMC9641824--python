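"""ASV-table preprocessing: decontamination, taxon filters, depth floor,
rarefaction.

The ladder runs in narrative order: prevalence-based contaminant flagging
against negative controls, removal of non-bacterial / organelle / unresolved
taxa, a minimum read-depth floor, and rarefaction without replacement to a
common depth.  Re-running the ladder on its own output is a no-op.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class AsvTable:
    """Samples x taxa count table with taxonomy and control flags."""

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    is_control: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("sample/taxon ids must be unique")
        if self.is_control is None:
            self.is_control = pd.Series(False, index=self.counts.index)
        self.is_control = self.is_control.reindex(self.counts.index, fill_value=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def drop_taxa(self, taxa) -> "AsvTable":
        keep = [t for t in self.counts.columns if t not in set(taxa)]
        tax = self.taxonomy.loc[self.taxonomy.index.isin(keep)] if self.taxonomy is not None else None
        return AsvTable(self.counts[keep], tax, self.is_control)

    def drop_controls(self) -> "AsvTable":
        keep = ~self.is_control
        return AsvTable(self.counts.loc[keep], self.taxonomy, self.is_control.loc[keep])


@dataclasses.dataclass
class PrepConfig:
    decontam_threshold: float = 0.5
    min_depth: int = 10_000
    rarefaction_seed: int = 999
    rarefaction_depth: int | None = None  # None -> post-filter minimum depth

    def __post_init__(self) -> None:
        if not 0 < self.decontam_threshold < 1:
            raise ValueError("decontam_threshold must lie in (0, 1)")
        if self.min_depth <= 0:
            raise ValueError("min_depth must be > 0")


def contaminant_score(k_ctrl: int, n_ctrl: int, k_true: int, n_true: int) -> float:
    """Prevalence-method score for one taxon: a presence/absence contingency
    p-value contrasting controls against true samples.

    The chi-square statistic (without continuity correction) is used unless
    any expected cell count falls below 5, in which case the one-sided
    Fisher exact (hypergeometric) p for control enrichment is returned.
    """
    table = np.array([[k_ctrl, n_ctrl - k_ctrl], [k_true, n_true - k_true]])
    expected = stats.contingency.expected_freq(table) if table.sum() else np.zeros((2, 2))
    if (expected < 5).any():
        return float(stats.fisher_exact(table, alternative="greater")[1])
    return float(stats.chi2_contingency(table, correction=False)[1])


def flag_contaminants(table: AsvTable, config: PrepConfig | None = None) -> pd.Series:
    """Per-taxon contaminant flag from negative controls.

    A taxon is flagged when it is proportionally more prevalent in controls
    than in true samples and its contingency score falls below the threshold.
    Taxa absent everywhere are never flagged (with a warning).
    """
    config = config or PrepConfig()
    ctrl = table.counts.loc[table.is_control] > 0
    true = table.counts.loc[~table.is_control] > 0
    if len(ctrl) < 1 or len(true) < 1:
        raise ValueError("need at least one control and one true sample")
    flags = pd.Series(False, index=table.counts.columns)
    absent = ~(ctrl.any() | true.any())
    if absent.any():
        warnings.warn(f"{int(absent.sum())} taxa absent everywhere; not flagged")
    for taxon in table.counts.columns[~absent]:
        kc, kt = int(ctrl[taxon].sum()), int(true[taxon].sum())
        if kc / len(ctrl) <= kt / len(true):
            continue  # not control-enriched
        score = contaminant_score(kc, len(ctrl), kt, len(true))
        flags[taxon] = score < config.decontam_threshold
    return flags


def taxon_filter(table: AsvTable, taxonomy: pd.DataFrame | None = None) -> tuple[AsvTable, dict]:
    """Remove non-bacterial, organelle-derived, and phylum-unresolved taxa."""
    taxonomy = taxonomy if taxonomy is not None else table.taxonomy
    if taxonomy is None:
        raise ValueError("taxonomy required")
    missing = [t for t in table.taxon_ids if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxonomy does not cover taxa: {missing[:5]}")
    tax = taxonomy.loc[table.taxon_ids]

    def unresolved(col: pd.Series) -> pd.Series:
        return col.isna() | (col.astype(str).str.strip() == "") | (
            col.astype(str).str.lower().isin({"na", "unresolved", "unclassified"})
        )

    rules = {
        "non_bacteria": tax["Kingdom"] != "Bacteria",
        "mitochondria": tax["Family"] == "Mitochondria",
        "chloroplast": tax["Order"] == "Chloroplast",
        "unresolved_phylum": unresolved(tax["Phylum"]),
    }
    removed = pd.Series(False, index=tax.index)
    log = {}
    for name, mask in rules.items():
        log[name] = int((mask & ~removed).sum())
        removed |= mask
    log["removed_total"] = int(removed.sum())
    return table.drop_taxa(tax.index[removed]), log


def depth_filter(table: AsvTable, config: PrepConfig | None = None) -> AsvTable:
    """Drop samples whose total reads fall below the minimum depth
    (samples at exactly the floor are retained)."""
    config = config or PrepConfig()
    depths = table.counts.sum(axis=1)
    keep = depths >= config.min_depth
    if not keep.any():
        raise ValueError("all samples below the minimum read depth")
    return AsvTable(table.counts.loc[keep], table.taxonomy, table.is_control.loc[keep])


def rarefy(counts: pd.DataFrame, depth: int, seed: int = 999) -> pd.DataFrame:
    """Subsample each sample's reads without replacement to exactly ``depth``.

    Multivariate-hypergeometric draw per sample; taxa with zero total after
    subsampling are removed.  Deterministic given the seed.
    """
    totals = counts.sum(axis=1)
    low = totals[totals < depth]
    if len(low):
        raise ValueError(f"samples below rarefaction depth {depth}: {list(low.index)[:5]}")
    rng = np.random.default_rng(seed)
    mat = counts.to_numpy(dtype=np.int64)
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        out[i] = rng.multivariate_hypergeometric(mat[i], depth)
    result = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return result.loc[:, result.sum(axis=0) > 0]


def prep_ladder(table: AsvTable, config: PrepConfig | None = None) -> tuple[AsvTable, dict]:
    """Full preprocessing: decontaminate -> taxon filter -> depth floor -> rarefy."""
    config = config or PrepConfig()
    log: dict = {"n_input_samples": len(table.counts), "n_input_taxa": len(table.counts.columns)}
    if table.is_control.any() and (~table.is_control).any():
        flags = flag_contaminants(table, config)
        log["n_contaminants"] = int(flags.sum())
        table = table.drop_taxa(flags.index[flags]).drop_controls()
    else:
        log["n_contaminants"] = 0
        table = table.drop_controls()
    if table.taxonomy is not None:
        table, tax_log = taxon_filter(table)
        log["taxon_filter"] = tax_log
    table = depth_filter(table, config)
    log["n_samples_after_depth"] = len(table.counts)
    depth = config.rarefaction_depth or int(table.counts.sum(axis=1).min())
    log["rarefaction_depth"] = depth
    rare = rarefy(table.counts, depth, config.rarefaction_seed)
    log["n_taxa_after_rarefaction"] = rare.shape[1]
    tax = table.taxonomy.loc[table.taxonomy.index.isin(rare.columns)] if table.taxonomy is not None else None
    return AsvTable(rare, tax, table.is_control), log
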