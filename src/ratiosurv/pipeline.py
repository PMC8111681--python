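"""End-to-end orchestration: normalize -> QC -> network -> differential
expression -> survival screens -> nomination -> combinatorial ratio screen,
with a stage manifest and a human-readable report.

Randomness flows from a single seed; every stage writes its table (when an
output directory is configured) and records a content hash in the manifest,
so reruns are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures
from .containers import (ExpressionMatrix, NormalizationSpec, SurvivalData,
                         TraitTable, normalize, read_expression_matrix,
                         read_survival, read_trait_table,
                         remove_outlier_samples)
from .diffexpr import DEGCriteria, consistency_filter, count_degs, ttest_groups
from .network import CoexpressionNetwork, NetworkConfig
from .ratio import RatioScreen, ScreenConfig, assemble_pools, enumerate_ratios
from .survival import (NominationRules, eigengene_survival_screen,
                       gene_survival_screen, nomination_filter)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression_path: str | None = None
    traits_path: str | None = None
    survival_path: str | None = None
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    outlier_z_cut: float = -2.5
    network: NetworkConfig = field(default_factory=NetworkConfig)
    deg_criteria: DEGCriteria = field(default_factory=DEGCriteria)
    nomination: NominationRules = field(default_factory=NominationRules)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    top_degs_per_module: int = 20
    #: cap per nomination panel (best log-rank p first); keeps the round-1
    #: enumeration near the study's ~1e5-combination scale
    max_panel_size: int = 12
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a pipeline configuration from a YAML file.

        Nested sections (``normalization``, ``network``, ``deg_criteria``,
        ``nomination``, ``screen``) map onto the corresponding config
        objects; scalar keys map onto this dataclass directly.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sections = {"normalization": NormalizationSpec,
                    "network": NetworkConfig,
                    "deg_criteria": DEGCriteria,
                    "nomination": NominationRules,
                    "screen": ScreenConfig}
        kwargs = {}
        for key, value in raw.items():
            if key in sections:
                if key == "screen":
                    for tup in ("sizes", "horizons"):
                        if tup in value:
                            value[tup] = tuple(value[tup])
                kwargs[key] = sections[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.10g").encode()).hexdigest()[:16]


class Manifest(dict):
    """Stage ledger: name -> {status, info, hash}."""

    def record(self, stage: str, status: str, info=None, table=None,
               outdir=None, seed=None) -> None:
        entry = {"status": status, "info": info}
        if table is not None:
            entry["hash"] = _hash_frame(table)
            if outdir is not None:
                path = Path(outdir) / f"{stage}.tsv"
                with open(path, "w") as fh:
                    from ratiosurv import __version__
                    fh.write(f"# ratiosurv {__version__} seed={seed}\n")
                    table.to_csv(fh, sep="\t")
                entry["path"] = str(path)
        self[stage] = entry


def run_pipeline(cfg: PipelineConfig,
                 data: tuple[ExpressionMatrix, TraitTable, SurvivalData] | None = None
                 ) -> Manifest:
    """Run all stages; returns the manifest (tables attached in ``_tables``).

    ``data`` may supply in-memory (expression, traits, survival) instead of
    the configured file paths.  Stages whose inputs are unavailable are
    skipped with an explicit manifest entry.
    """
    man = Manifest()
    tables: dict = {}
    man["_tables"] = tables
    outdir = cfg.outdir
    if outdir:
        Path(outdir).mkdir(parents=True, exist_ok=True)

    if data is not None:
        expr, traits, surv = data
    else:
        if cfg.expression_path is None:
            raise ValueError("no expression input configured")
        expr = read_expression_matrix(cfg.expression_path)
        traits = read_trait_table(cfg.traits_path) if cfg.traits_path else None
        surv = read_survival(cfg.survival_path) if cfg.survival_path else None

    expr = normalize(expr, cfg.normalization)
    expr, excluded = remove_outlier_samples(expr, cfg.outlier_z_cut)
    man.record("normalize_qc", "ok",
               info={"excluded_samples": excluded, "n_samples": expr.n_samples})

    net = CoexpressionNetwork(expr, cfg.network).fit()
    tables["modules"] = pd.DataFrame({
        "module": net.modules.labels,
        "own_kme": [net.kme.kme.at[g, m] if m in net.kme.kme.columns else np.nan
                    for g, m in net.modules.labels.items()],
        "hub": net.kme.hub,
    })
    man.record("network", "ok",
               info={"n_modules": len(net.modules.sizes())},
               table=tables["modules"], outdir=outdir, seed=cfg.seed)
    tables["eigengenes"] = net.eigengenes.values
    man.record("eigengenes", "ok", table=net.eigengenes.values,
               outdir=outdir, seed=cfg.seed)

    if traits is not None and "subtype" in traits.table.columns:
        stats_df = net.trait_stats(traits)
        tables["module_traits"] = stats_df
        man.record("module_traits", "ok", table=stats_df, outdir=outdir,
                   seed=cfg.seed)
        deg_results = []
        present = set(expr.sample_ids)
        tn = [s for s in traits.subtype_samples("TNBC") if s in present]
        for other in ("LumA", "LumB", "HER2"):
            grp = [s for s in traits.subtype_samples(other) if s in present]
            if len(tn) < 2 or len(grp) < 2:
                man.record(f"deg_TNBC_vs_{other}", "skipped",
                           info="too few samples")
                continue
            res = ttest_groups(expr, tn, grp, comparison=f"TNBC_vs_{other}")
            deg_results.append(res)
            up, down = count_degs(res, cfg.deg_criteria)
            tables[f"deg_TNBC_vs_{other}"] = res
            man.record(f"deg_TNBC_vs_{other}", "ok",
                       info={"n_up": up, "n_down": down},
                       table=res, outdir=outdir, seed=cfg.seed)
        if len(deg_results) == 3:
            consistent = consistency_filter(deg_results, cfg.deg_criteria)
            man.record("consistency_filter", "ok",
                       info={"n_consistent": len(consistent)})
            tables["consistent_degs"] = pd.DataFrame({"gene": consistent})
    else:
        man.record("module_traits", "skipped", info="no trait table")
        deg_results = []

    if surv is None:
        man.record("survival_screen", "skipped", info="no survival data")
        man.record("ratio_screen", "skipped", info="no survival data")
        return man

    me_screen = eigengene_survival_screen(net.eigengenes, surv)
    tables["eigengene_survival"] = me_screen
    man.record("eigengene_survival", "ok", table=me_screen, outdir=outdir,
               seed=cfg.seed)

    # side assignment: the most TNBC-anticorrelated module is the numerator
    # (down-in-TNBC, good-prognosis) side; the most positively correlated is
    # the denominator side — mirroring the anticorrelated module duo.
    num_panel: list = []
    den_panel: list = []
    if traits is not None and "TNBC" in traits.table.columns and deg_results:
        mt = tables["module_traits"]
        tn_corr = (mt[mt["trait"] == "TNBC"]
                   .set_index("module")["bicor"].sort_values())
        if len(tn_corr) < 2:
            man.record("nomination", "skipped",
                       info="need two modules to define the ratio sides")
            man.record("ratio_screen", "skipped", info="no nomination")
            return man
        num_mod, den_mod = tn_corr.index[0], tn_corr.index[-1]
        res = deg_results[0]
        labels = net.modules.labels
        cand = {}
        for side, mod in (("M2", num_mod), ("M12", den_mod)):
            members = labels.index[labels == mod]
            sub = res.loc[res.index.intersection(members)]
            sub = sub.reindex(sub["q"].sort_values().index)
            cand[side] = list(sub.index[:cfg.top_degs_per_module])
        screen_genes = cand["M2"] + cand["M12"]
        gene_screen = gene_survival_screen(expr, screen_genes, surv)
        tables["gene_survival"] = gene_screen
        man.record("gene_survival", "ok", table=gene_screen, outdir=outdir,
                   seed=cfg.seed)
        nom_frame = pd.DataFrame({
            "gene": screen_genes,
            "side": ["M2"] * len(cand["M2"]) + ["M12"] * len(cand["M12"]),
            "logrank_p": gene_screen.loc[screen_genes, "p"].to_numpy(),
            "probe": True,
        })
        num_panel, den_panel = nomination_filter(nom_frame, cfg.nomination)
        pvals = nom_frame.set_index("gene")["logrank_p"]
        num_panel = sorted(num_panel, key=pvals.get)[:cfg.max_panel_size]
        den_panel = sorted(den_panel, key=pvals.get)[:cfg.max_panel_size]
        man.record("nomination", "ok",
                   info={"numerator": num_panel, "denominator": den_panel})
    if not num_panel or not den_panel:
        man.record("ratio_screen", "skipped",
                   info="empty nomination panel(s)")
        return man

    screen = RatioScreen(expr, surv, num_panel, den_panel, cfg.screen).fit()
    tables["ratio_screen"] = screen.table
    tables["_screen_result"] = screen
    man.record("ratio_screen", "ok",
               info={"n_combinations": len(screen.specs)},
               table=screen.table, outdir=outdir, seed=cfg.seed)
    return man


def fixture_counts() -> dict:
    """Reproduce the in-study worked-example counts from packaged fixtures.

    Returns the nomination panel sizes, round-1 enumeration totals and
    round-2 pool sizes, all recomputed from the packaged tables by the
    same code paths the pipeline uses.
    """
    t2 = fixtures.rfs_screen_fixture()
    rules = NominationRules(
        alternate_platform_overrides={"OPRK1": fixtures.OPRK1_ARRAY_P})
    num, den = nomination_filter(t2, rules)
    specs = enumerate_ratios(num, den, ScreenConfig(include_full=False))
    specs_full = enumerate_ratios(num, den, ScreenConfig(include_full=True))
    nsrc, dsrc = fixtures.round2_recipe()
    pool_n, pool_d = assemble_pools(nsrc, dsrc)
    return {
        "numerator_panel": num,
        "denominator_panel": den,
        "round1_combinations": len(specs),
        "round1_combinations_with_full": len(specs_full),
        "round2_numerator_pool": len(pool_n),
        "round2_denominator_pool": len(pool_d),
    }


def report(man: Manifest) -> str:
    """Deterministic markdown summary of a completed manifest."""
    lines = ["# ratiosurv pipeline report", ""]
    for stage, entry in man.items():
        if stage.startswith("_"):
            continue
        lines.append(f"## {stage}")
        lines.append(f"status: {entry['status']}")
        info = entry.get("info")
        if info:
            lines.append(f"info: {json.dumps(info, default=str, sort_keys=True)}")
        if "hash" in entry:
            lines.append(f"hash: {entry['hash']}")
        lines.append("")
    tables = man.get("_tables", {})
    screen = tables.get("_screen_result")
    if screen is not None:
        lines.append("## top ratio combinations")
        top = screen.top(10)[["numerator", "denominator", "max_auc",
                              "mean_auc", "rank"]]
        lines.append(top.to_string(index=False))
    elif man.get("ratio_screen", {}).get("status") != "ok":
        lines.append("no combinations evaluated")
    lines.append("")
    return "\n".join(lines)
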