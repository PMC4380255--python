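"""Greedy two-pass clustering of flowgrams with weighted-average centers.

Pass 1 scans reads in input order; each read joins the first existing
cluster whose center it matches at every overlapping flow position (or
founds a new cluster), and the center is updated as a running weighted
mean.  Because centers move, pass 2 re-assigns every read against the
*frozen* final centers, tried from the most populous cluster down, so reads
map to the largest cluster that will have them.  A read matching no frozen
center founds a singleton appended after the sorted list.

Every (center value, read value) pair judged significantly different during
either pass is recorded into a binned 2-D histogram of "misses" — the
diagnostic used to judge whether the denoising distance suits the dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceModel, distinct
from .sffio import read_flowgrams

log = logging.getLogger(__name__)

Flowgram = Sequence[float]


class MissMatrix:
    """Binned 2-D histogram over (center flow value, read flow value) pairs
    judged distinct during denoising.  Bin width 0.01 over [0, 10], clamped.
    """

    def __init__(self, bin_width: float = 0.01, vmax: float = 10.0):
        self.bin_width = bin_width
        self.vmax = vmax
        self.nbins = int(round(vmax / bin_width)) + 1
        self.counts = np.zeros((self.nbins, self.nbins), dtype=np.uint32)

    def _bin(self, v: float) -> int:
        return min(max(int(round(v / self.bin_width)), 0), self.nbins - 1)

    def record(self, center_value: float, read_value: float) -> None:
        self.counts[self._bin(center_value), self._bin(read_value)] += 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path) -> None:
        """Sparse TSV: center_value, read_value, count (nonzero cells only)."""
        ci, ri = np.nonzero(self.counts)
        with open(path, "w") as fh:
            fh.write("# center_value\tread_value\tcount\n")
            for c, r in zip(ci.tolist(), ri.tolist()):
                fh.write(
                    f"{c * self.bin_width:.2f}\t{r * self.bin_width:.2f}"
                    f"\t{int(self.counts[c, r])}\n"
                )

    def plot(self, path: str | Path) -> None:
        """Render the miss histogram as a levelplot image (needs matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        with np.errstate(divide="ignore"):
            img = np.log10(self.counts.T.astype(float))
        extent = (0, self.vmax, 0, self.vmax)
        im = ax.imshow(img, origin="lower", extent=extent, aspect="equal", cmap="turbo")
        fig.colorbar(im, ax=ax, label="log10 misses")
        ax.set_xlabel("cluster flow value")
        ax.set_ylabel("read flow value")
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class Cluster:
    """A denoising cluster: per-position weighted-mean flow values.

    ``counts[p]`` is the number of members whose flowgram extends past
    position p (members may be shorter than the center), so it is
    non-increasing in p and the center at p is the arithmetic mean of the
    values of those members.
    """

    center: list[float] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)
    members: list[tuple[str, int]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    def add(self, read_id: str, flows: Flowgram) -> None:
        overlap = min(len(flows), len(self.center))
        for p in range(overlap):
            c = self.counts[p]
            self.center[p] = (self.center[p] * c + flows[p]) / (c + 1)
            self.counts[p] = c + 1
        for p in range(len(self.center), len(flows)):
            self.center.append(float(flows[p]))
            self.counts.append(1)
        self.members.append((read_id, len(flows)))


def match_cluster(
    read_flows: Flowgram,
    cluster: Cluster,
    model: DistanceModel,
    misses: Optional[MissMatrix] = None,
) -> bool:
    """True iff no overlapping position is significantly different.

    A length difference alone never rejects: comparison runs over the
    overlap only (the read is reconstituted at its own length later).  The
    scan stops at the first failing position, which is recorded as a miss.
    """
    return _match(read_flows, cluster.center, model, misses)


def _match(read_flows, center, model, misses) -> bool:
    for p in range(min(len(read_flows), len(center))):
        if distinct(model, center[p], read_flows[p]):
            if misses is not None:
                misses.record(center[p], read_flows[p])
            return False
    return True


def pass1(
    reads: Sequence[tuple[str, Flowgram]],
    model: DistanceModel,
    misses: Optional[MissMatrix] = None,
) -> list[Cluster]:
    """Build clusters greedily in input order with evolving centers."""
    clusters: list[Cluster] = []
    for rid, flows in reads:
        for cl in clusters:
            if _match(flows, cl.center, model, misses):
                cl.add(rid, flows)
                break
        else:
            cl = Cluster()
            cl.add(rid, flows)
            clusters.append(cl)
    return clusters


def pass2(
    reads: Sequence[tuple[str, Flowgram]],
    clusters: Sequence[Cluster],
    model: DistanceModel,
    misses: Optional[MissMatrix] = None,
) -> tuple[list[Cluster], dict[str, int]]:
    """Re-assign every read against frozen centers sorted by pass-1 size.

    Ties in size break by creation order.  Orphans (reads matching no frozen
    center) found singleton clusters appended after the sorted list; empty
    clusters are dropped from the output.  Returns the final cluster list
    (members = pass-2 assignment) and the read -> cluster-index map.
    """
    order = sorted(range(len(clusters)), key=lambda i: (-clusters[i].size, i))
    finals: list[Cluster] = [
        Cluster(
            center=list(clusters[i].center),
            counts=list(clusters[i].counts),
            members=[],
        )
        for i in order
    ]
    assignment: dict[str, int] = {}
    for rid, flows in reads:
        for idx, cl in enumerate(finals):
            if _match(flows, cl.center, model, misses):
                # frozen centers: record membership without recalculating,
                # except singletons appended during this pass, whose center
                # is their founding read
                cl.members.append((rid, len(flows)))
                assignment[rid] = idx
                break
        else:
            cl = Cluster()
            cl.add(rid, flows)  # singleton: its own flowgram is the center
            finals.append(cl)
            assignment[rid] = len(finals) - 1
    # drop clusters that attracted no reads in pass 2 and renumber
    keep = [i for i, cl in enumerate(finals) if cl.members]
    remap = {old: new for new, old in enumerate(keep)}
    finals = [finals[i] for i in keep]
    assignment = {rid: remap[i] for rid, i in assignment.items()}
    return finals, assignment


@dataclass
class DenoiseResult:
    clusters: list[Cluster]
    assignment: dict[str, int]
    misses: MissMatrix
    read_flow_lengths: dict[str, int]
    flow_chars: str = ""
    phase: int = 0
    bin_label: str = ""

    @property
    def center_flowgrams(self) -> dict[int, list[float]]:
        return {i: cl.center for i, cl in enumerate(self.clusters)}


def denoise_reads(
    reads: Sequence[tuple[str, Flowgram]],
    model: DistanceModel,
    record_misses: bool = True,
) -> DenoiseResult:
    """Run both clustering passes over in-memory (id, flowgram) pairs."""
    misses = MissMatrix()
    recorder = misses if record_misses else None
    clusters = pass1(reads, model, recorder)
    finals, assignment = pass2(reads, clusters, model, recorder)
    return DenoiseResult(
        clusters=finals,
        assignment=assignment,
        misses=misses,
        read_flow_lengths={rid: len(flows) for rid, flows in reads},
    )


def denoise_bin(
    flowgram_file: str | Path,
    model: DistanceModel,
    record_misses: bool = True,
) -> DenoiseResult:
    """Denoise one filtered flowgram bin file by clustering."""
    meta, entries = read_flowgrams(flowgram_file)
    result = denoise_reads(entries, model, record_misses)
    result.flow_chars = meta.get("flow_order", "")
    result.phase = int(meta.get("phase", 0))
    result.bin_label = meta.get("bin", Path(flowgram_file).stem)
    log.info(
        "bin %s: %d reads -> %d clusters (%d misses)",
        result.bin_label, len(entries), len(result.clusters), result.misses.total,
    )
    return result
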