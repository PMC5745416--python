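"""End-to-end orchestration over datasets and collections.

A dataset run applies the full battery: ILD and IRD permutation tests
of hard/soft partition homogeneity, and (when a reference tree is
available) the molecular-consistency comparison of retention indices.
A collection run maps this over a manifest, then combines p-values per
clade and overall with Fisher's method, applies a Bonferroni-corrected
clade-family threshold, and fits the between/within ANOVAs on partition
retention indices.  Every stage is seeded from one master seed through
named substreams, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .characters import CharacterMatrix
from .consistency import ConsistencyResult, consistency_test
from .errors import (
    ConfigError,
    CoverageError,
    DegeneratePartitionError,
    PhylopartError,
    ValidationError,
)
from .incongruence import PermutationTestResult, partition_homogeneity_tests
from .io import (
    ManifestEntry,
    read_manifest,
    read_newick_tree,
    read_nexus_matrix,
    write_results,
)
from .meta import (
    AnovaResult,
    BonferroniResult,
    FisherResult,
    MixedAnovaResult,
    anova_between,
    anova_mixed,
    bonferroni_alpha,
    fishers_combined,
)
from .search import SearchConfig, parsimony_search

TESTS = ("ILD", "IRD", "MWW")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a dataset or collection run."""

    reps: int = 999
    alpha: float = 0.05
    search: SearchConfig = field(default_factory=SearchConfig)
    master_seed: int = 0
    informative_only_ild: bool = True
    ird_direction: str = "both"
    min_shared_taxa: int = 10

    def __post_init__(self):
        if self.reps < 99:
            raise ConfigError("reps must be >= 99 for pipeline runs")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        if self.ird_direction not in ("both", "a_to_b"):
            raise ConfigError("ird_direction must be 'both' or 'a_to_b'")


@dataclass(frozen=True)
class DatasetResult:
    dataset_id: str
    clade: str
    ild: PermutationTestResult | None = None
    ird: PermutationTestResult | None = None
    consistency: ConsistencyResult | None = None
    error: str | None = None
    notes: tuple = ()
    audit: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MetaSummary:
    """Clade-level and overall combinations plus the RI ANOVAs."""

    per_test: dict
    corrected_alpha: BonferroniResult | None
    anova_between: AnovaResult | None
    anova_mixed: MixedAnovaResult | None
    n_datasets: int


@dataclass(frozen=True)
class CollectionResult:
    results: tuple
    rows: tuple
    meta: MetaSummary


def _small(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def analyze_dataset(
    matrix: CharacterMatrix,
    reference,
    config: RunConfig,
    seed: int | None = None,
) -> DatasetResult:
    """Run the full per-dataset battery on in-memory objects."""
    seed = config.master_seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_tests, s_audit = ss.spawn(2)
    notes = []
    ild = ird = cons = None
    try:
        ild, ird = partition_homogeneity_tests(
            matrix,
            reps=config.reps,
            search=config.search,
            seed=_small(s_tests),
            informative_only=config.informative_only_ild,
            direction=config.ird_direction,
            which="both",
        )
    except (DegeneratePartitionError, ValidationError) as exc:
        notes.append(f"partition tests skipped: {exc}")
    if reference is not None:
        try:
            cons = consistency_test(
                matrix, reference, min_shared=config.min_shared_taxa
            )
        except (CoverageError, DegeneratePartitionError) as exc:
            notes.append(f"consistency skipped: {exc}")
    else:
        notes.append("consistency skipped: no reference tree")

    audit = {}
    if ild is not None:
        a_h, a_s = s_audit.spawn(2)
        for name, subset, sub_ss in (
            ("hard", matrix.hard_indices, a_h),
            ("soft", matrix.soft_indices, a_s),
        ):
            try:
                ts = parsimony_search(
                    matrix, subset,
                    config=config.search.with_seed(_small(sub_ss)),
                )
                audit[name] = {
                    "score": ts.score,
                    "n_trees": len(ts),
                    "capped": ts.capped,
                }
            except PhylopartError:
                pass
    return DatasetResult(
        dataset_id=matrix.dataset_id,
        clade=matrix.clade,
        ild=ild,
        ird=ird,
        consistency=cons,
        notes=tuple(notes),
        audit=audit,
    )


def run_dataset(
    matrix_path,
    tree_path=None,
    config: RunConfig | None = None,
    dataset_id: str | None = None,
    clade: str = "",
    partition_spec: dict | None = None,
    seed: int | None = None,
) -> DatasetResult:
    """Run the battery on files; failures become an error row."""
    config = config or RunConfig()
    did = dataset_id or Path(matrix_path).stem
    try:
        matrix = read_nexus_matrix(
            matrix_path, partition_spec=partition_spec,
            dataset_id=did, clade=clade,
        )
        reference = (
            read_newick_tree(tree_path) if tree_path is not None else None
        )
    except PhylopartError as exc:
        return DatasetResult(dataset_id=did, clade=clade, error=str(exc))
    return analyze_dataset(matrix, reference, config, seed=seed)


def result_row(r: DatasetResult) -> dict:
    """Flatten one dataset result into the 7-field table row."""
    return {
        "dataset_id": r.dataset_id,
        "clade": r.clade,
        "ild_p": None if r.ild is None else r.ild.p_value,
        "ird_p": None if r.ird is None else r.ird.p_value,
        "mww_p": None if r.consistency is None else r.consistency.mww_p,
        "RI_hard": None if r.consistency is None else r.consistency.RI_hard,
        "RI_soft": None if r.consistency is None else r.consistency.RI_soft,
    }


def summarize_rows(rows: Sequence[dict], alpha: float = 0.05) -> MetaSummary:
    """Combine per-dataset rows: Fisher per clade and overall, Bonferroni
    threshold, and ANOVAs of partition retention indices."""
    rows = list(rows)
    clades = sorted({r["clade"] for r in rows if r.get("clade")})
    per_test = {}
    key_of = {"ILD": "ild_p", "IRD": "ird_p", "MWW": "mww_p"}
    for test in TESTS:
        key = key_of[test]
        pvals = [
            (r["clade"], r[key]) for r in rows if r.get(key) is not None
        ]
        overall = fishers_combined([p for _, p in pvals]) if pvals else None
        by_clade = {}
        for clade in clades:
            ps = [p for c, p in pvals if c == clade]
            if ps:
                by_clade[clade] = fishers_combined(ps)
        order = sorted(by_clade, key=lambda c: (by_clade[c].p, c))
        per_test[test] = {
            "overall": overall,
            "by_clade": by_clade,
            "clade_order": order,
        }
    corrected = bonferroni_alpha(alpha, len(clades)) if clades else None

    cons_rows = [
        r for r in rows
        if r.get("RI_hard") is not None and r.get("RI_soft") is not None
    ]
    between = mixed = None
    if cons_rows:
        values = [(r["RI_hard"] + r["RI_soft"]) / 2.0 for r in cons_rows]
        groups = [r["clade"] for r in cons_rows]
        try:
            between = anova_between(values, groups)
        except ValidationError:
            between = None
        try:
            mixed = anova_mixed(
                [r["RI_hard"] for r in cons_rows],
                [r["RI_soft"] for r in cons_rows],
                groups,
            )
        except ValidationError:
            mixed = None
    return MetaSummary(
        per_test=per_test,
        corrected_alpha=corrected,
        anova_between=between,
        anova_mixed=mixed,
        n_datasets=len(rows),
    )


def run_collection(
    manifest_path,
    config: RunConfig | None = None,
    out_dir=None,
    partition_spec: dict | None = None,
) -> CollectionResult:
    """Run every dataset in a manifest and combine the results.

    With ``out_dir`` set, writes ``results.tsv``, the meta-analysis
    summary and a run record holding configuration, every substream
    seed, search audits and the full permutation null distributions.
    """
    config = config or RunConfig()
    entries = read_manifest(manifest_path)
    if not entries:
        raise ValidationError("empty manifest")
    seeds = np.random.SeedSequence(config.master_seed).spawn(len(entries))
    results = []
    for entry, sub in zip(entries, seeds):
        results.append(
            run_dataset(
                entry.matrix_path,
                entry.tree_path,
                config=config,
                dataset_id=entry.dataset_id,
                clade=entry.clade,
                partition_spec=partition_spec,
                seed=_small(sub),
            )
        )
    rows = [result_row(r) for r in results]
    meta = summarize_rows(rows, alpha=config.alpha)
    if out_dir is not None:
        record = run_record(config, entries, results, meta)
        write_results(rows, out_dir, run_record=record)
    return CollectionResult(
        results=tuple(results), rows=tuple(rows), meta=meta
    )


def meta_to_dict(meta: MetaSummary) -> dict:
    out = {
        "n_datasets": meta.n_datasets,
        "per_test": {},
        "corrected_alpha": (
            None
            if meta.corrected_alpha is None
            else dataclasses.asdict(meta.corrected_alpha)
        ),
        "anova_between": (
            None
            if meta.anova_between is None
            else dataclasses.asdict(meta.anova_between)
        ),
        "anova_mixed": (
            None
            if meta.anova_mixed is None
            else dataclasses.asdict(meta.anova_mixed)
        ),
    }
    for test, block in meta.per_test.items():
        out["per_test"][test] = {
            "overall": (
                None
                if block["overall"] is None
                else dataclasses.asdict(block["overall"])
            ),
            "by_clade": {
                c: dataclasses.asdict(f)
                for c, f in block["by_clade"].items()
            },
            "clade_order": list(block["clade_order"]),
        }
    return out


def run_record(config, entries, results, meta) -> dict:
    """Machine-readable record of a collection run."""
    rec = {
        "config": {
            "reps": config.reps,
            "alpha": config.alpha,
            "master_seed": config.master_seed,
            "informative_only_ild": config.informative_only_ild,
            "ird_direction": config.ird_direction,
            "min_shared_taxa": config.min_shared_taxa,
            "search": dataclasses.asdict(config.search),
        },
        "datasets": {},
        "meta": meta_to_dict(meta),
    }
    for r in results:
        d = {
            "clade": r.clade,
            "error": r.error,
            "notes": list(r.notes),
            "audit": r.audit,
        }
        for name, t in (("ild", r.ild), ("ird", r.ird)):
            if t is not None:
                d[name] = {
                    "observed": t.observed,
                    "p_value": t.p_value,
                    "tail": t.tail,
                    "seed": t.seed,
                    "replicates": t.replicates,
                    "null_values": list(t.null_values),
                }
        if r.consistency is not None:
            d["consistency"] = dataclasses.asdict(r.consistency)
        rec["datasets"][r.dataset_id] = d
    return rec
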