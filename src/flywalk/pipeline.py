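"""End-to-end orchestration: features per fly, group statistics, manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, _as_plain_dict
from .features import FEATURE_NAMES, extract_features, feature_table
from .stats import (
    CVAResults,
    TestPanel,
    pairwise_correlations,
    pca_variance,
    permutation_test,
    ranksum_panel,
)
from .trajectory import Trajectory


@dataclass
class PipelineResult:
    features: pd.DataFrame
    panel: TestPanel | None
    correlations: pd.DataFrame | None
    pca_fractions: np.ndarray | None
    cva: CVAResults | None
    excluded: pd.DataFrame
    manifest: dict


def run_pipeline(
    groups: dict[str, list[Trajectory]],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    reference_group: str | None = None,
) -> PipelineResult:
    """Features → rank-sum panel → correlations → PCA → CVA + permutation.

    ``groups`` maps group label → trajectories. With ≥ 2 groups the rank-sum
    panel compares the first two (or ``reference_group`` against the rest
    pooled pairwise is out of scope — panels are pairwise), and CVA uses all
    groups. Writes TSV tables and a manifest if ``out_dir`` is given.
    """
    config = config or PipelineConfig()
    if not groups or not any(groups.values()):
        raise ValueError("no input trajectories")
    vectors = []
    for label, trajs in groups.items():
        for traj in trajs:
            vectors.append(extract_features(traj, config, group=label))
    table = feature_table(vectors)
    excluded = table[table["excluded"]][["fly_id", "group"]].copy()
    excluded["reason"] = [
        next(iter(fv.reasons.values()), "") for fv in vectors if fv.excluded
    ]
    usable = table[~table["excluded"]]

    panel = correlations = cva_res = None
    fractions = None
    labels = usable["group"].to_numpy()
    if len(groups) >= 2:
        names = list(groups)
        ga = usable[usable["group"] == names[0]][FEATURE_NAMES]
        gb = usable[usable["group"] == names[1]][FEATURE_NAMES]
        if len(ga) >= 3 and len(gb) >= 3:
            panel = ranksum_panel(ga, gb, alpha=config.alpha)
    ref = reference_group or next(iter(groups))
    ref_rows = usable[usable["group"] == ref][FEATURE_NAMES]
    if len(ref_rows) >= 5:
        correlations = pairwise_correlations(ref_rows, alpha=config.alpha)
    complete = usable[FEATURE_NAMES].dropna()
    if len(complete) >= 2:
        fractions, _ = pca_variance(
            usable[FEATURE_NAMES], standardize=config.standardize_pca
        )
    if len(groups) >= 2:
        counts = pd.Series(labels).value_counts()
        if len(counts) >= 2 and counts.min() >= 2:
            try:
                cva_res = permutation_test(
                    usable[FEATURE_NAMES],
                    labels,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                    ridge=config.ridge,
                )
            except ValueError:
                cva_res = None

    manifest = {
        "flywalk_version": __version__,
        "python": platform.python_version(),
        "config": _as_plain_dict(config),
        "config_hash": hashlib.sha256(
            json.dumps(_as_plain_dict(config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "groups": {k: len(v) for k, v in groups.items()},
        "n_excluded": int(table["excluded"].sum()),
        "seed": config.seed,
        "n_permutations": config.n_permutations,
    }

    result = PipelineResult(
        features=table,
        panel=panel,
        correlations=correlations,
        pca_fractions=fractions,
        cva=cva_res,
        excluded=excluded,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_results(result, Path(out_dir))
    return result


def _write_results(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    res.features.to_csv(out / "features.tsv", sep="\t", index=False, float_format="%.6g")
    res.excluded.to_csv(out / "excluded.tsv", sep="\t", index=False)
    if res.panel is not None:
        res.panel.table.to_csv(out / "ranksum_panel.tsv", sep="\t", index=False)
    if res.correlations is not None:
        res.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    if res.pca_fractions is not None:
        pd.DataFrame(
            {
                "component": np.arange(1, len(res.pca_fractions) + 1),
                "variance_fraction": res.pca_fractions,
            }
        ).to_csv(out / "pca_variance.tsv", sep="\t", index=False, float_format="%.6g")
    if res.cva is not None:
        (out / "cva_summary.txt").write_text(res.cva.summary() + "\n")
        pd.DataFrame(
            {"group": res.cva.groups, "cv1": res.cva.projections[:, 0]}
        ).to_csv(out / "cva_projections.tsv", sep="\t", index=False, float_format="%.6g")
        if res.cva.null_distances is not None:
            pd.DataFrame({"distance": res.cva.null_distances}).to_csv(
                out / "cva_null_distances.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True)
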