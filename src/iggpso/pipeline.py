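"""End-to-end hybrid selection: rank by IG, group, grouped swarm search."""

from __future__ import annotations

from dataclasses import dataclass, field

from .dataio import ExpressionDataset
from .evaluation import EvalProtocol
from .gpso import GPSOConfig, SelectionResult, run_gpso
from .grouping import FeatureGroups, group_count, partition_features
from .infogain import DiscretizationScheme, RankedFeatures, rank_features

__all__ = ["ig_gpso_select"]


def ig_gpso_select(
    dataset: ExpressionDataset,
    gamma: int = 100,
    scheme: DiscretizationScheme | None = None,
    config: GPSOConfig | None = None,
    protocol: EvalProtocol | None = None,
) -> SelectionResult:
    """Run the full hybrid selector on a dataset.

    Features are ranked by information gain, partitioned into
    ``k = ceil(n_features / gamma)`` contiguous groups of roughly equal
    total IG, and searched by the grouping binary PSO wrapper.
    """
    if scheme is None:
        scheme = DiscretizationScheme()
    if config is None:
        config = GPSOConfig()
    if protocol is None:
        protocol = EvalProtocol()
    ranked = rank_features(dataset, scheme)
    k = group_count(dataset.n_features, gamma)
    groups = partition_features(ranked, k)
    return run_gpso(groups, dataset, config, protocol)
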