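"""One-command end-to-end analysis: indices, PD panels, switch and co-occurrence.

``run`` reproduces the full analysis layout for a record table and a host
tree: the complete network plus one network per requested realm, each with
its index row, PD profiles sorted by adult PD, switch-rate and stage-flow
tables, co-occurrence classifications, a GraphML dump, and a machine-readable
manifest recording inputs, seeds and the decisions in force.  The Oriental
realm is excluded from switch tables by default (too few species with all
three stages known there to support the statistic); an override is provided.
No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .build import BuildOptions, EmptyNetworkError, HostRank, TickGranularity, build_network, to_matrix
from .cooccurrence import cooccurrence_matrix, pairs_to_frame
from .metrics import NetworkIndexReport, network_report
from .network import write_graphml
from .ontogeny import flow_to_frame, stage_flow, switch_rates_to_frame, switch_table
from .pd import pd_profiles, profiles_to_frame
from .records import AssociationRecord, Realm, read_records
from .trees import Phylogeny, read_tree

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run", "compare_with_reference"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    records_path: str
    tree_path: str
    out_dir: str
    tree_format: str = "newick"
    realms: tuple[Realm, ...] = ()
    host_rank: HostRank = HostRank.FAMILY
    tick_granularity: TickGranularity = TickGranularity.SPECIES
    seed: int = 0
    extinction_replicates: int = 100
    louvain_restarts: int = 10
    cooccurrence_alpha: float = 0.05
    include_oriental_switch: bool = False

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["realms"] = tuple(Realm(r) for r in raw.get("realms", ()))
        if "host_rank" in raw:
            raw["host_rank"] = HostRank(raw["host_rank"])
        if "tick_granularity" in raw:
            raw["tick_granularity"] = TickGranularity(raw["tick_granularity"])
        return RunConfig(**raw)


@dataclass
class RunResult:
    """Index rows per network plus the output manifest."""

    reports: dict[str, NetworkIndexReport] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _analyze_one(
    label: str,
    records: Sequence[AssociationRecord],
    tree: Phylogeny,
    realm: Realm | None,
    cfg: RunConfig,
    out: Path,
) -> NetworkIndexReport:
    opts = BuildOptions(
        host_rank=cfg.host_rank,
        realm_filter=realm,
        tick_granularity=cfg.tick_granularity,
    )
    net = build_network(records, opts)
    write_graphml(net, out / f"network_{label}.graphml")

    report = network_report(
        net,
        seed=cfg.seed,
        n_replicates=cfg.extinction_replicates,
        louvain_restarts=cfg.louvain_restarts,
    )

    profiles = pd_profiles(records, tree, realm=realm)
    profiles_to_frame(profiles, sort_by_adult_pd=True).to_csv(
        out / f"pd_{label}.csv", index=False
    )

    if realm is None or realm != Realm.ORIENTAL or cfg.include_oriental_switch:
        rates, n_skipped = switch_table(profiles, realm=realm)
        switch_rates_to_frame(rates).to_csv(out / f"switch_{label}.csv", index=False)
        if n_skipped:
            logger.info("%s: %d species lacked two consecutive stages", label, n_skipped)
        flow_records = (
            records if realm is None else [r for r in records if r.realm == realm]
        )
        flow_to_frame(stage_flow(flow_records, realm=realm)).to_csv(
            out / f"flow_{label}.csv", index=False
        )

    matrix = to_matrix(net, host_rank_restriction="family")
    pairs_to_frame(cooccurrence_matrix(matrix, alpha=cfg.cooccurrence_alpha)).to_csv(
        out / f"cooccurrence_{label}.csv", index=False
    )
    return report


def run(cfg: RunConfig) -> RunResult:
    """Execute the full analysis; any stage failure aborts naming the stage.

    Partial outputs written before a failure are preserved on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_records(cfg.records_path)
    tree = read_tree(cfg.tree_path, format=cfg.tree_format)

    result = RunResult()
    networks: list[tuple[str, Realm | None]] = [("complete", None)]
    networks += [(r.value, r) for r in cfg.realms]
    for label, realm in networks:
        try:
            result.reports[label] = _analyze_one(label, records, tree, realm, cfg, out)
        except EmptyNetworkError:
            logger.warning("network %s is empty; skipped", label)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {label!r} failed: {exc}") from exc

    table = pd.DataFrame(
        {label: rep.to_dict() for label, rep in result.reports.items()}
    )
    table.to_csv(out / "index_table.csv")
    with open(out / "index_table.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in result.reports.items()}, fh, indent=2)

    result.manifest = {
        "version": __version__,
        "records_path": str(cfg.records_path),
        "tree_path": str(cfg.tree_path),
        "tree_format": cfg.tree_format,
        "realms": [r.value for r in cfg.realms],
        "host_rank": cfg.host_rank.value,
        "tick_granularity": cfg.tick_granularity.value,
        "seed": cfg.seed,
        "extinction_replicates": cfg.extinction_replicates,
        "louvain_restarts": cfg.louvain_restarts,
        "cooccurrence_alpha": cfg.cooccurrence_alpha,
        "include_oriental_switch": cfg.include_oriental_switch,
        "decisions": {
            "matrix_indices_on_family_rank": True,
            "nodf_on_binary_view": True,
            "betweenness_paths": "unweighted",
            "extinction_removal_order": "uniform_random",
            "multiple_testing_correction": "none",
            "pd_include_root": True,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    return result


def compare_with_reference(
    report: NetworkIndexReport, reference: dict[str, float]
) -> pd.DataFrame:
    """Side-by-side computed vs reference index values.

    ``reference`` maps index names (as in :class:`NetworkIndexReport`) to
    published or otherwise expected values; unknown keys are ignored with a
    warning so partial reference tables are usable.
    """
    computed = report.to_dict()
    rows = []
    for key, ref in reference.items():
        if key not in computed:
            logger.warning("reference key %r is not a known index; ignored", key)
            continue
        val = computed[key]
        rows.append(
            {
                "index": key,
                "computed": val,
                "reference": ref,
                "abs_diff": val - ref,
                "rel_diff": (val - ref) / ref if ref else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["index", "computed", "reference", "abs_diff", "rel_diff"])
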