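"""End-to-end orchestration: simulate → dual-regress → masks → reliability.

Two entry points: :func:`run_in_memory` keeps everything in arrays (used by
the test-suite and the acceptance script), and :func:`run_pipeline` works
through the on-disk layout (NIfTI volumes + manifest) and writes the report
files a study analyst would archive.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as nio
from .dualreg import dual_regress
from .group import compare_groups
from .stats import dice_r12, network_reproducibility
from .synthetic import simulate_bold, simulate_dataset, write_dataset
from .types import (
    Bold4D,
    DegenerateInputError,
    SESSIONS,
    SimulationConfig,
    SubjectNetworkMaps,
    TemplateSet,
)

logger = logging.getLogger(__name__)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("stage %-12s %.2fs", stage, time.perf_counter() - self.t0)

    return _Timer()


def dual_regress_dataset(
    bolds: Iterable[Bold4D], templates: TemplateSet
) -> List[SubjectNetworkMaps]:
    maps = []
    for bold in bolds:
        try:
            maps.append(dual_regress(bold, templates))
        except Exception as exc:
            raise RuntimeError(
                f"dual regression failed for subject {bold.subject_id!r} "
                f"session {bold.session!r}: {exc}"
            ) from exc
    return maps


def per_subject_r12(
    subject_maps: Sequence[SubjectNetworkMaps],
    templates: TemplateSet,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Tidy per-subject Dice overlap: subject_id, group, network, r12."""
    by_subject: Dict[str, Dict[str, SubjectNetworkMaps]] = {}
    for m in subject_maps:
        by_subject.setdefault(m.subject_id, {})[m.session] = m
    rows = []
    for sid, pair in sorted(by_subject.items()):
        for j, name in enumerate(templates.names):
            try:
                res = dice_r12(pair["BL"].zmap[j], pair["FU"].zmap[j], threshold)
                r12 = res.r12
            except DegenerateInputError:
                r12 = np.nan
            rows.append(
                {
                    "subject_id": sid,
                    "group": pair["BL"].group,
                    "network": name,
                    "r12": r12,
                }
            )
    return pd.DataFrame(rows)


def group_comparison_table(
    r12_table: pd.DataFrame, m_tests: Optional[int] = None
) -> pd.DataFrame:
    """Between-group pooled t-tests of R12 per network (Bonferroni-flagged)."""
    networks = list(dict.fromkeys(r12_table["network"]))
    groups = sorted(r12_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    m = m_tests if m_tests is not None else len(networks)
    rows = []
    for name in networks:
        sub = r12_table[r12_table["network"] == name]
        a = sub.loc[sub["group"] == groups[0], "r12"].to_numpy()
        b = sub.loc[sub["group"] == groups[1], "r12"].to_numpy()
        cmp = compare_groups(a, b, m_tests=m, label=name)
        rows.append(
            {
                "network": name,
                f"{groups[0]}_mean": np.nanmean(a),
                f"{groups[0]}_sd": np.nanstd(a, ddof=1),
                f"{groups[1]}_mean": np.nanmean(b),
                f"{groups[1]}_sd": np.nanstd(b, ddof=1),
                "t": cmp.statistic,
                "df": cmp.df,
                "p": cmp.p,
                "significant_bonferroni": cmp.significant_bonferroni,
                "alpha_bonferroni": cmp.alpha_bonferroni,
            }
        )
    return pd.DataFrame(rows)


def run_in_memory(
    config: SimulationConfig,
    threshold: float = 0.0,
    en_threshold: float = 0.0,
) -> Tuple[pd.DataFrame, Dict]:
    """Simulate a study and compute its reliability tables without disk I/O.

    Returns the reproducibility table plus a dict of intermediates
    (templates, truth, subject_maps, r12 table, group comparison table).
    """
    with _timed("simulate"):
        templates, truth = simulate_dataset(config)
        bolds = [
            simulate_bold(truth, templates, config, i, s)
            for i in range(truth.n_subjects)
            for s in range(len(SESSIONS))
        ]
    with _timed("dualreg"):
        subject_maps = dual_regress_dataset(bolds, templates)
    with _timed("repro"):
        group_labels = dict(zip(truth.subject_ids, truth.group_labels))
        repro = network_reproducibility(
            subject_maps, templates, group_labels, threshold, en_threshold
        )
        r12_table = per_subject_r12(subject_maps, templates, threshold)
        comparison = (
            group_comparison_table(r12_table)
            if r12_table["group"].nunique() == 2
            else None
        )
    extras = {
        "templates": templates,
        "truth": truth,
        "subject_maps": subject_maps,
        "r12_table": r12_table,
        "group_comparison": comparison,
    }
    return repro, extras


def load_bolds(manifest: pd.DataFrame, templates: TemplateSet, tr_seconds: float = 3.0):
    bolds = []
    for _, row in manifest.iterrows():
        data, _ = nio.read_volume(row["path"])
        nio.check_grid(data, templates.grid_dims, what=f"BOLD {row['path']}")
        bolds.append(
            Bold4D(
                data=data,
                tr_seconds=tr_seconds,
                subject_id=row["subject_id"],
                session=row["session"],
                group=row["group"],
            )
        )
    return bolds


def run_pipeline(
    config: SimulationConfig,
    out_dir,
    manifest: Optional[pd.DataFrame] = None,
    templates: Optional[TemplateSet] = None,
    threshold: float = 0.0,
    en_threshold: float = 0.0,
    write_maps: bool = True,
) -> Dict[str, Path]:
    """Run the full on-disk pipeline and write report files.

    Without a manifest the study is simulated from ``config`` and written
    under ``out_dir/data`` first.  Outputs: per-subject beta/Z maps
    (optional), ``report.csv`` (per-network reliability) and
    ``group_comparison.csv`` (between-group R12 t-tests).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        with _timed("simulate"):
            templates, truth = simulate_dataset(config)
            manifest = write_dataset(truth, templates, config, out_dir / "data")
    elif templates is None:
        raise ValueError("a templates set is required when a manifest is given")
    nio.validate_manifest(manifest)

    with _timed("dualreg"):
        bolds = load_bolds(manifest, templates, config.tr_seconds)
        subject_maps = dual_regress_dataset(bolds, templates)
    if write_maps:
        maps_dir = out_dir / "maps"
        maps_dir.mkdir(exist_ok=True)
        for m in subject_maps:
            prefix = maps_dir / f"sub-{m.subject_id}_ses-{m.session}"
            nio.write_volume(
                np.moveaxis(m.beta, 0, -1), templates.affine, f"{prefix}_beta.nii.gz"
            )
            nio.write_volume(
                np.moveaxis(m.zmap, 0, -1), templates.affine, f"{prefix}_z.nii.gz"
            )

    with _timed("repro"):
        group_labels = dict(zip(manifest["subject_id"], manifest["group"]))
        repro = network_reproducibility(
            subject_maps, templates, group_labels, threshold, en_threshold
        )
        r12_table = per_subject_r12(subject_maps, templates, threshold)
    report_path = out_dir / "report.csv"
    repro.to_csv(report_path, index=False, float_format="%.10g")
    outputs = {"report": report_path}
    if r12_table["group"].nunique() == 2:
        comparison = group_comparison_table(r12_table)
        cmp_path = out_dir / "group_comparison.csv"
        comparison.to_csv(cmp_path, index=False, float_format="%.10g")
        outputs["group_comparison"] = cmp_path
    r12_path = out_dir / "r12_by_subject.csv"
    r12_table.to_csv(r12_path, index=False, float_format="%.10g")
    outputs["r12_by_subject"] = r12_path
    return outputs
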