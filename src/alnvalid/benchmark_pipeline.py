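"""End-to-end benchmark orchestration.

Four steps: (1) assemble a labeled dataset by pooling per-family FASTA
files, dropping any sequence claimed by more than one family; (2) draw the
resampling replicates (90% without replacement, 10 times, by default);
(3) run each configured alignment method — the internal all-pairs PSA or an
external MSA program invoked through an argument template — and turn its
output into a distance matrix; (4) score every (dataset, method) pair with
SW and RS and compare methods across replicates with a t-test.

All randomness flows from one top-level seed through named numpy
SeedSequence sub-streams, so a fixed seed plus fixed inputs reproduces the
replicate draws — and, with the internal PSA, the entire report — exactly.
"""

from __future__ import annotations

import logging
import math
import shlex
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_validity import evaluate
from .containers import DistanceMatrix, LabeledDataset, SequenceSet
from .errors import ContractError, IntegrityError, ToolError
from .identity_distance import msa_distance_matrix
from .io_formats import PathLike, read_fasta, write_fasta
from .pairwise_align import ScoreParams, all_pairs_distances

logger = logging.getLogger(__name__)

KINDS = ("internal-psa", "external-msa")


@dataclass(frozen=True)
class MethodConfig:
    """One alignment method: the internal PSA or an external MSA program.

    External commands are argument templates; ``{input}`` is replaced by the
    unaligned FASTA path and, if present, ``{output}`` by the path the tool
    should write its aligned FASTA to — otherwise stdout is parsed.
    """

    name: str
    kind: str = "internal-psa"
    params: ScoreParams = field(default_factory=ScoreParams)
    command: tuple[str, ...] = ()
    gap_policy: str = "keep-all"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ContractError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "external-msa" and not self.command:
            raise ContractError(f"method {self.name!r}: external-msa needs a command template")

    def resolve_executable(self) -> str:
        exe = shutil.which(self.command[0])
        if exe is None:
            raise ToolError(f"method {self.name!r}: executable {self.command[0]!r} not found")
        return exe


@dataclass(frozen=True)
class BenchmarkGroup:
    """One benchmark group: the assembled dataset plus its resampling replicates."""

    name: str
    original: LabeledDataset
    resamples: tuple[LabeledDataset, ...]
    seed: int

    @property
    def datasets(self) -> list[tuple[str, LabeledDataset]]:
        """(dataset name, dataset) pairs: the original then each replicate."""
        out = [(f"{self.name}/original", self.original)]
        out += [(f"{self.name}/resample{k + 1}", ds) for k, ds in enumerate(self.resamples)]
        return out


@dataclass(frozen=True)
class ComparisonResult:
    """Welch (or paired) t-test between two per-replicate score vectors."""

    method_a: str
    method_b: str
    score_name: str
    scores_a: tuple[float, ...]
    scores_b: tuple[float, ...]
    mean_difference: float
    p_value: float


def build_benchmark_group(family_files: Sequence[tuple[str, PathLike]]) -> LabeledDataset:
    """Pool per-family FASTA files into one labeled dataset.

    A sequence id appearing under more than one family is excluded entirely
    (it cannot carry a single class label); duplicates within one family
    keep the first record. Exclusions are logged.
    """
    if len(family_files) < 2:
        raise ContractError("need at least 2 family files")
    memberships: dict[str, set[str]] = {}
    records: dict[str, tuple[str, str]] = {}  # id -> (family, residues)
    for fam, path in family_files:
        sset = read_fasta(path, aligned=False)
        if len(sset) == 0:
            raise ContractError(f"family {fam!r}: empty file {path}")
        for seq in sset:
            memberships.setdefault(seq.id, set()).add(fam)
            records.setdefault(seq.id, (fam, seq.residues))
    excluded = sorted(i for i, fams in memberships.items() if len(fams) > 1)
    for sid in excluded:
        logger.warning(
            "excluding %r: belongs to families %s", sid, sorted(memberships[sid])
        )
    kept = [sid for sid in records if sid not in set(excluded)]
    if not kept:
        raise ContractError("all sequences excluded as multi-family; dataset is empty")
    from .containers import ProteinSequence

    seqs = [ProteinSequence(sid, records[sid][1], records[sid][0]) for sid in kept]
    return LabeledDataset(SequenceSet(seqs))


def resample(
    ds: LabeledDataset, fraction: float = 0.9, reps: int = 10, seed: int = 0
) -> list[LabeledDataset]:
    """*reps* unstratified draws of floor(fraction * n) sequences, without
    replacement, labels carried through; deterministic under *seed*."""
    if not 0 < fraction <= 1:
        raise ContractError(f"fraction must be in (0, 1], got {fraction}")
    if reps < 1:
        raise ContractError(f"reps must be >= 1, got {reps}")
    n = len(ds)
    k = math.floor(fraction * n)
    if k < 2:
        raise ContractError(f"replicate size floor({fraction}*{n}) = {k} < 2")
    ids = ds.sequences.ids
    out = []
    for child in np.random.SeedSequence(seed).spawn(reps):
        rng = np.random.default_rng(child)
        idx = np.sort(rng.choice(n, size=k, replace=False))  # keep original order
        out.append(ds.subset([ids[i] for i in idx]))
    return out


def make_group(
    name: str, ds: LabeledDataset, fraction: float = 0.9, reps: int = 10, seed: int = 0
) -> BenchmarkGroup:
    """Attach the resampling replicates to *ds* under a group-derived seed."""
    group_seed = int(np.random.SeedSequence([seed, _stable_hash(name)]).generate_state(1)[0] % (2**31))
    return BenchmarkGroup(
        name=name,
        original=ds,
        resamples=tuple(resample(ds, fraction=fraction, reps=reps, seed=group_seed)),
        seed=group_seed,
    )


def _stable_hash(text: str) -> int:
    # process-independent (PYTHONHASHSEED-proof) 31-bit hash of a group name
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def plan_runs(
    groups: Iterable[BenchmarkGroup], cfgs: Sequence[MethodConfig]
) -> list[tuple[str, str]]:
    """The full run schedule: one (dataset name, method name) job per
    alignment analysis. Counting this list is the bookkeeping check for a
    study design (e.g. 8 groups x 11 datasets x 7 methods = 616 runs)."""
    return [
        (ds_name, cfg.name)
        for g in groups
        for ds_name, _ in g.datasets
        for cfg in cfgs
    ]


def run_method(
    ds: LabeledDataset, cfg: MethodConfig, workdir: PathLike | None = None
) -> DistanceMatrix:
    """Produce the method's distance matrix for one dataset.

    Internal PSA: all-pairs Needleman-Wunsch. External MSA: write the
    unaligned FASTA, invoke the tool, parse its aligned FASTA (stdout or the
    ``{output}`` file), check sequence integrity, and project pairwise
    identities. Matrix ids always equal the dataset's ids, in order.
    """
    if cfg.kind == "internal-psa":
        return all_pairs_distances(ds.sequences, cfg.params)

    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx else Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    try:
        in_path = wd / "input.fasta"
        out_path = wd / "aligned.fasta"
        write_fasta(ds.sequences, in_path)
        argv = [
            a.replace("{input}", str(in_path)).replace("{output}", str(out_path))
            for a in cfg.command
        ]
        uses_output_file = any("{output}" in a for a in cfg.command)
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ToolError(
                f"method {cfg.name!r}: {shlex.join(argv)} exited {proc.returncode}",
                stdout=proc.stdout,
                stderr=proc.stderr,
            )
        if not uses_output_file:
            out_path.write_text(proc.stdout)
        aln = read_fasta(out_path, aligned=True)
        missing = sorted(set(ds.sequences.ids) - set(aln.ids))
        extra = sorted(set(aln.ids) - set(ds.sequences.ids))
        if missing or extra:
            raise IntegrityError(
                f"method {cfg.name!r}: aligned output missing ids {missing}, unexpected {extra}"
            )
        for sid in ds.sequences.ids:
            if aln.row(sid).replace("-", "") != ds.sequences[sid].residues:
                raise IntegrityError(
                    f"method {cfg.name!r}: degapped output for {sid!r} differs from input"
                )
        return msa_distance_matrix(aln.reordered(ds.sequences.ids), cfg.gap_policy)
    finally:
        if ctx:
            ctx.cleanup()


def evaluate_group(
    group: BenchmarkGroup,
    cfgs: Sequence[MethodConfig],
    ss_w_center: str = "cluster",
    workdir: PathLike | None = None,
    matrix_dir: PathLike | None = None,
) -> pd.DataFrame:
    """SW/RS score table for every (dataset, method) pair of one group.

    Rows: (1 + reps) datasets x len(cfgs) methods. When *matrix_dir* is
    given, every computed distance matrix is also written there as TSV.
    Errors are re-raised tagged with the dataset and method that produced
    them.
    """
    if not cfgs:
        logger.warning("group %r: no methods configured; empty score table", group.name)
    if matrix_dir is not None:
        Path(matrix_dir).mkdir(parents=True, exist_ok=True)
    rows = []
    for ds_name, ds in group.datasets:
        for cfg in cfgs:
            try:
                dmat = run_method(ds, cfg, workdir=workdir)
                res = evaluate(dmat, ds.labels, ss_w_center=ss_w_center)
            except Exception as e:
                raise type(e)(f"[dataset {ds_name!r}, method {cfg.name!r}] {e}") from e
            if matrix_dir is not None:
                from .io_formats import write_distance_matrix

                safe = ds_name.replace("/", "_")
                write_distance_matrix(dmat, Path(matrix_dir) / f"{safe}.{cfg.name}.dist.tsv")
            rows.append(
                {
                    "group": group.name,
                    "dataset": ds_name,
                    "method": cfg.name,
                    "n": res.n,
                    "sw": res.sw,
                    "rs": res.rs,
                }
            )
    return pd.DataFrame(rows, columns=["group", "dataset", "method", "n", "sw", "rs"])


def compare_methods(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    method_a: str = "A",
    method_b: str = "B",
    score_name: str = "SW",
    paired: bool = False,
) -> ComparisonResult:
    """Two-sided t-test (Welch by default, paired optional) between two
    per-replicate score vectors. Identical vectors give p = 1 by convention;
    a nonzero mean difference with zero variance gives p = 0."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ContractError(
            f"score vectors must be equal-length 1-D with length >= 2, got {a.shape} vs {b.shape}"
        )
    if np.array_equal(a, b):
        p = 1.0
    else:
        if paired:
            p = float(stats.ttest_rel(a, b).pvalue)
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if math.isnan(p):  # both vectors constant but different
            p = 0.0
    return ComparisonResult(
        method_a=method_a,
        method_b=method_b,
        score_name=score_name,
        scores_a=tuple(a),
        scores_b=tuple(b),
        mean_difference=float(a.mean() - b.mean()),
        p_value=p,
    )


def compare_all(
    scores: pd.DataFrame, paired: bool = False, resamples_only: bool = True
) -> list[ComparisonResult]:
    """All method-pair comparisons per group and score from an
    :func:`evaluate_group` table (replicate rows only, by default)."""
    out: list[ComparisonResult] = []
    tab = scores[~scores["dataset"].str.endswith("/original")] if resamples_only else scores
    for group, gtab in tab.groupby("group", sort=False):
        methods = list(dict.fromkeys(gtab["method"]))
        for i, ma in enumerate(methods):
            for mb in methods[i + 1 :]:
                for score_name in ("sw", "rs"):
                    va = gtab.loc[gtab["method"] == ma, score_name].to_numpy()
                    vb = gtab.loc[gtab["method"] == mb, score_name].to_numpy()
                    out.append(
                        compare_methods(
                            va, vb, f"{group}:{ma}", f"{group}:{mb}",
                            score_name=score_name.upper(), paired=paired,
                        )
                    )
    return out


def report(
    scores: pd.DataFrame, comparisons: Sequence[ComparisonResult], outdir: PathLike
) -> dict[str, Path]:
    """Write the score table, comparison table and best-method summary as
    TSV with 6-decimal scores; byte-identical across re-runs on identical
    inputs."""
    if scores.empty:
        raise ContractError("score table is empty; nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"scores": outdir / "scores.tsv"}
    scores.to_csv(paths["scores"], sep="\t", index=False, float_format="%.6f")

    resamp = scores[~scores["dataset"].str.endswith("/original")]
    basis = resamp if not resamp.empty else scores
    summary_rows = []
    for group, gtab in basis.groupby("group", sort=False):
        means = gtab.groupby("method", sort=False)[["sw", "rs"]].mean()
        for score_name in ("sw", "rs"):
            best = means[score_name].idxmax()
            summary_rows.append(
                {
                    "group": group,
                    "score": score_name.upper(),
                    "best_method": best,
                    "mean": means.loc[best, score_name],
                }
            )
    paths["summary"] = outdir / "summary.tsv"
    pd.DataFrame(summary_rows).to_csv(
        paths["summary"], sep="\t", index=False, float_format="%.6f"
    )

    if comparisons:
        comp_rows = [
            {
                "method_a": c.method_a,
                "method_b": c.method_b,
                "score": c.score_name,
                "mean_difference": c.mean_difference,
                "p_value": c.p_value,
            }
            for c in comparisons
        ]
        paths["comparisons"] = outdir / "comparisons.tsv"
        pd.DataFrame(comp_rows).to_csv(
            paths["comparisons"], sep="\t", index=False, float_format="%.6g"
        )
    return paths
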