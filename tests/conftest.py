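"""Shared fixtures: a seed-fixed benchmark simulation run once per session."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pytest
from hypothesis import settings

import ampliflow as af
from ampliflow.synthgen import SimConfig, read_truth, write_run

settings.register_profile("suite", derandomize=True, max_examples=50, database=None)
settings.load_profile("suite")


@dataclass
class Benchmark:
    """The standard synthetic benchmark: 200 reads from 5 references of
    length 250 at the default (moderate) sd table, filtered with the common
    length/ambiguity/window recipe, denoised by clustering at several
    constant distances."""

    run: object
    filter_run: object
    truth: dict
    pre: dict                     # filtered read id -> sequence
    refs_path: Path
    by_j: dict = field(default_factory=dict)  # j -> (n_clusters, denoised, purity_ok)


def _denoise_all(filter_run, model):
    total_clusters = 0
    denoised: dict[str, str] = {}
    assignment_by_read: dict[str, tuple[str, int]] = {}
    for label, path in filter_run.bin_paths.items():
        res = af.denoise_bin(path, model)
        total_clusters += len(res.clusters)
        order = af.FlowOrder(res.flow_chars, 10**9)
        policy = af.CallPolicy(order)
        for rid, seq, _ in af.reconstitute_all(
            res.assignment, res.center_flowgrams, res.read_flow_lengths,
            policy, res.phase,
        ):
            denoised[rid] = seq
        for rid, cid in res.assignment.items():
            assignment_by_read[rid] = (label, cid)
    return total_clusters, denoised, assignment_by_read


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory) -> Benchmark:
    outdir = tmp_path_factory.mktemp("benchmark")
    cfg = SimConfig(seed=1, n_references=5, ref_length=250, reads_per_ref=40)
    run = write_run(cfg, outdir)
    samples = af.read_sample_sheet(run.sample_sheet_path)
    filter_run = af.run_filter(
        run.sff_path, samples, af.FilterConfig.standard(), outdir / "filtered"
    )
    bench = Benchmark(
        run=run,
        filter_run=filter_run,
        truth=read_truth(run.truth_path),
        pre=af.read_fasta(filter_run.fasta_path),
        refs_path=run.refs_path,
    )
    for j in (0.3, 0.5, 0.7, 0.9):
        model = af.DistanceModel.constant(j)
        n_clusters, denoised, assignment = _denoise_all(filter_run, model)
        purity_ok = _purity(bench.truth, assignment)
        bench.by_j[j] = (n_clusters, denoised, purity_ok, assignment)
    return bench


def _purity(truth, assignment):
    """True iff reads of one reference always share a cluster and reads of
    different references never do."""
    ref_to_cluster: dict[str, tuple] = {}
    cluster_to_ref: dict[tuple, str] = {}
    for rid, key in assignment.items():
        ref = truth[rid][1]
        if ref_to_cluster.setdefault(ref, key) != key:
            return False
        if cluster_to_ref.setdefault(key, ref) != ref:
            return False
    return True
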