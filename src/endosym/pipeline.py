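"""Orchestration: pair manifest -> tables, sign tests, and figures.

The manifest is the machine-readable mirror of a published pair table: one
row per symbiont/organelle record and its free-living relative, with an
optional ``group`` column that merges partnerships regarded as reflecting
the same case (each merged group then contributes a single observation per
feature to the sign test).  All statistics are computed by the
:mod:`endosym.comparison` module; this layer only plumbs files, metadata and
figures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import comparison as cmp
from .properties import FEATURES, PropertyTable, load_property_table
from .seq_io import GenomeProfile, profile_genome, profile_to_frame, read_proteins

__all__ = [
    "ManifestEntry",
    "PairManifest",
    "read_manifest",
    "run_analysis",
    "make_figure",
]

logger = logging.getLogger(__name__)

#: Features entering the headline sign test.  Carboxyl pKa is computed and
#: exported for every gene but excluded here: no retention direction is
#: predicted for it.
DEFAULT_TEST_FEATURES: tuple[str, ...] = ("hydrophobicity", "amino_pka")

PAIR_COLUMNS = [
    "symbiont_id",
    "relative_id",
    "feature",
    "symbiont_mean",
    "relative_mean",
    "difference",
    "predicted_sign",
    "agrees",
    "group",
]


@dataclass
class ManifestEntry:
    pair_id: str
    symbiont_path: Path
    symbiont_label: str
    relative_path: Path
    relative_label: str
    group: str = ""
    notes: str = ""


@dataclass
class PairManifest:
    entries: list[ManifestEntry]
    table_source: str | None = None

    def __post_init__(self) -> None:
        ids = [e.pair_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("pair_id values must be unique")

    def validate_paths(self) -> None:
        missing = [
            str(p)
            for e in self.entries
            for p in (e.symbiont_path, e.relative_path)
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError("manifest paths not found: " + ", ".join(missing))


def read_manifest(path: str | Path) -> PairManifest:
    """Read a pair manifest from TSV (default) or JSON.

    TSV columns: pair_id, symbiont_path, symbiont_label, relative_path,
    relative_label, and optionally group and notes.  Relative paths are
    resolved against the manifest's own directory.
    """
    path = Path(path)
    base = path.parent

    def resolve(p: str) -> Path:
        candidate = Path(p)
        return candidate if candidate.is_absolute() else base / candidate

    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        entries = [
            ManifestEntry(
                pair_id=str(e["pair_id"]),
                symbiont_path=resolve(e["symbiont_path"]),
                symbiont_label=str(e["symbiont_label"]),
                relative_path=resolve(e["relative_path"]),
                relative_label=str(e["relative_label"]),
                group=str(e.get("group", "") or ""),
                notes=str(e.get("notes", "") or ""),
            )
            for e in payload["entries"]
        ]
        return PairManifest(entries=entries, table_source=payload.get("table_source"))
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {
        "pair_id",
        "symbiont_path",
        "symbiont_label",
        "relative_path",
        "relative_label",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"manifest is missing column(s): {sorted(missing)}")
    entries = [
        ManifestEntry(
            pair_id=row["pair_id"],
            symbiont_path=resolve(row["symbiont_path"]),
            symbiont_label=row["symbiont_label"],
            relative_path=resolve(row["relative_path"]),
            relative_label=row["relative_label"],
            group=row.get("group", ""),
            notes=row.get("notes", ""),
        )
        for _, row in frame.iterrows()
    ]
    return PairManifest(entries=entries)


def _detect_format(path: Path) -> str:
    return "genbank" if path.suffix.lower() in (".gb", ".gbk", ".gbff") else "fasta"


def _load_profile(path: Path, label: str, role: str, table: PropertyTable) -> GenomeProfile:
    skipped: list[tuple[str, str]] = []
    records = read_proteins(path, _detect_format(path), skipped=skipped)
    return profile_genome(records, table, organism_id=label, role=role, n_skipped=len(skipped))


def run_analysis(
    manifest: PairManifest,
    features: tuple[str, ...] = DEFAULT_TEST_FEATURES,
    merge: bool = False,
    table: PropertyTable | None = None,
    outdir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Run the full paired analysis over a manifest.

    Returns a result bundle (per-gene, per-pair, sign-test, correlation and
    stratified DataFrames plus run metadata); when ``outdir`` is given the
    bundle is also written as TSV/JSON files.  All inputs are read and
    scored before any output is written, so an unreadable input aborts with
    nothing partial on disk.
    """
    if not manifest.entries:
        raise ValueError("manifest contains no pairs")
    unknown = [f for f in features if f not in FEATURES]
    if unknown:
        raise ValueError(f"unknown feature(s) requested: {unknown}")
    if not features:
        raise ValueError("at least one feature must be requested")
    manifest.validate_paths()
    if table is None:
        table = load_property_table(manifest.table_source)

    profiles: list[tuple[ManifestEntry, GenomeProfile, GenomeProfile]] = []
    for entry in manifest.entries:
        symbiont = _load_profile(entry.symbiont_path, entry.symbiont_label, "symbiont", table)
        relative = _load_profile(entry.relative_path, entry.relative_label, "relative", table)
        profiles.append((entry, symbiont, relative))

    per_gene = pd.concat(
        [profile_to_frame(p) for _, s, r in profiles for p in (s, r)],
        ignore_index=True,
    )

    comparisons: list[cmp.PairComparison] = []
    pair_rows = []
    merge_groups: dict[str, str] = {}
    for entry, symbiont, relative in profiles:
        for feature in features:
            comp = cmp.compare_pair(symbiont, relative, feature)
            comparisons.append(comp)
            pair_rows.append(
                {
                    "symbiont_id": comp.symbiont_id,
                    "relative_id": comp.relative_id,
                    "feature": comp.feature,
                    "symbiont_mean": comp.symbiont_mean,
                    "relative_mean": comp.relative_mean,
                    "difference": comp.difference,
                    "predicted_sign": comp.predicted_sign,
                    "agrees": comp.agrees,
                    "group": entry.group,
                }
            )
        if entry.group:
            merge_groups[f"{entry.symbiont_label}~{entry.relative_label}"] = entry.group
    pairs_frame = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)

    sign_rows = []
    unmerged = cmp.sign_test(comparisons)
    sign_rows.append(
        {"k": unmerged.k, "n": unmerged.n, "p_value": unmerged.p_value, "grouping": unmerged.grouping}
    )
    merged_result = None
    if merge and merge_groups:
        merged_result = cmp.sign_test(comparisons, merge_groups=merge_groups)
        sign_rows.append(
            {
                "k": merged_result.k,
                "n": merged_result.n,
                "p_value": merged_result.p_value,
                "grouping": merged_result.grouping,
            }
        )
    sign_frame = pd.DataFrame(sign_rows, columns=["k", "n", "p_value", "grouping"])

    all_profiles = [p for _, s, r in profiles for p in (s, r)]
    metadata: dict = {
        "table_name": table.name,
        "table_provenance": table.provenance,
        "package_version": _pkg_version("endosym"),
        "seed": seed,
        "features": list(features),
        "merge": merge,
        "n_pairs": len(manifest.entries),
        "n_skipped": {p.organism_id: p.n_skipped for p in all_profiles},
        "degenerate": [],
    }
    corr_frame = pd.DataFrame(
        columns=["feature_x", "feature_y", "r_squared", "n_genes", "method"]
    )
    try:
        corr = cmp.gene_correlation(all_profiles, "hydrophobicity", "amino_pka")
        corr_frame = pd.DataFrame(
            [
                {
                    "feature_x": corr.feature_x,
                    "feature_y": corr.feature_y,
                    "r_squared": corr.r_squared,
                    "n_genes": corr.n_genes,
                    "method": corr.method,
                }
            ]
        )
    except (ValueError, cmp.DegenerateCorrelationError) as exc:
        metadata["degenerate"].append(f"gene_correlation: {exc}")

    strat_rows = []
    for profile in all_profiles:
        for stratum in cmp.stratified_summary(profile):
            row = {
                "organism_id": profile.organism_id,
                "role": profile.role,
                "stratum": stratum.stratum,
                "count": stratum.count,
            }
            for feature in FEATURES:
                row[f"mean_{feature}"] = (
                    stratum.means[feature] if stratum.means else float("nan")
                )
            strat_rows.append(row)
    strat_frame = pd.DataFrame(strat_rows)

    bundle = {
        "per_gene": per_gene,
        "pairs": pairs_frame,
        "sign_tests": sign_frame,
        "correlation": corr_frame,
        "stratified": strat_frame,
        "metadata": metadata,
        "comparisons": comparisons,
        "sign_result": unmerged,
        "sign_result_merged": merged_result,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_gene.to_csv(outdir / "per_gene.tsv", sep="\t", index=False)
        pairs_frame.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        sign_frame.to_csv(outdir / "signtest.tsv", sep="\t", index=False)
        corr_frame.to_csv(outdir / "correlation.tsv", sep="\t", index=False)
        strat_frame.to_csv(outdir / "stratified.tsv", sep="\t", index=False)
        (outdir / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    return bundle


def _infer_pairs(per_gene: pd.DataFrame) -> list[tuple[str, str]]:
    symbionts = per_gene.loc[per_gene["role"] == "symbiont", "organism_id"].unique()
    relatives = per_gene.loc[per_gene["role"] == "relative", "organism_id"].unique()
    return list(zip(symbionts, relatives))


def make_figure(
    per_gene: pd.DataFrame | str | Path,
    out_path: str | Path,
    pairs: list[tuple[str, str]] | None = None,
    features: tuple[str, ...] = DEFAULT_TEST_FEATURES,
    seed: int = 0,
) -> Path:
    """Paired boxplots with jittered per-gene points, one panel per feature.

    For each partnership the relative (blue) sits left and the symbiont
    (red) right.  Jitter positions come from ``seed``, so renders are
    reproducible.  ``pairs`` defaults to zipping symbionts and relatives in
    order of appearance.
    """
    if not isinstance(per_gene, pd.DataFrame):
        per_gene = pd.read_csv(per_gene, sep="\t")
    required = {"organism_id", "role"} | {f"mean_{f}" for f in features}
    missing = required - set(per_gene.columns)
    if missing:
        raise ValueError(f"per-gene table is missing column(s): {sorted(missing)}")
    if per_gene.empty:
        raise ValueError("per-gene table is empty")
    if pairs is None:
        pairs = _infer_pairs(per_gene)
    rng = np.random.default_rng(seed)
    colors = {"relative": "#3b6fb6", "symbiont": "#c23b3b"}
    fig, axes = plt.subplots(
        1, len(features), figsize=(max(6.0, 1.8 * len(pairs)) * len(features) / 2, 4.5),
        squeeze=False,
    )
    for ax, feature in zip(axes[0], features):
        column = f"mean_{feature}"
        positions, box_data, box_colors, labels = [], [], [], []
        for j, (symbiont_id, relative_id) in enumerate(pairs):
            for offset, organism, role in (
                (0.0, relative_id, "relative"),
                (0.8, symbiont_id, "symbiont"),
            ):
                values = per_gene.loc[
                    per_gene["organism_id"] == organism, column
                ].to_numpy()
                x = 2.0 * j + offset
                positions.append(x)
                box_data.append(values)
                box_colors.append(colors[role])
                jitter = rng.uniform(-0.18, 0.18, size=values.size)
                ax.scatter(
                    x + jitter, values, s=4, alpha=0.35, color=colors[role],
                    linewidths=0, zorder=1,
                )
            labels.append(f"{symbiont_id}\nvs {relative_id}")
        boxes = ax.boxplot(
            box_data, positions=positions, widths=0.55, showfliers=False,
            patch_artist=True, zorder=2,
        )
        for patch, color in zip(boxes["boxes"], box_colors):
            patch.set_facecolor("none")
            patch.set_edgecolor(color)
        for median in boxes["medians"]:
            median.set_color("black")
        ax.set_xticks([2.0 * j + 0.4 for j in range(len(pairs))])
        ax.set_xticklabels(labels, fontsize=7)
        ax.set_ylabel(f"mean {feature.replace('_', ' ')}")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
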