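"""Denoise filtered flowgrams by greedy clustering, then reconstitute reads.

Two passes: centers grow as weighted means of their members, then every
read is re-assigned against the frozen centers from the most populous
cluster down.  Each read's sequence is re-called from its cluster's
flowgram, truncated to the read's own flow count (no accordion effect),
with .50 flow values rounding down and dropout runs marked as N.
Run 01 and 02 first.
"""

from pathlib import Path

from ampliflow import (
    CallPolicy, DistanceModel, FlowOrder, denoise_bin,
    reconstitute_all, write_fasta,
)

outdir = Path("example_output/denoised")
outdir.mkdir(parents=True, exist_ok=True)
model = DistanceModel.constant(0.50)   # the classic constant distance

records = []
for bin_path in sorted(Path("example_output/filtered").glob("bin_*.flows.tsv")):
    result = denoise_bin(bin_path, model)
    sizes = sorted((c.size for c in result.clusters), reverse=True)
    print(f"{bin_path.name}: {len(result.assignment)} reads -> "
          f"{len(result.clusters)} clusters of sizes {sizes}; "
          f"{result.misses.total} misses recorded")
    result.misses.to_tsv(outdir / f"{result.bin_label}.misses.tsv")
    policy = CallPolicy(FlowOrder(result.flow_chars, 10 ** 9))
    records += list(reconstitute_all(
        result.assignment, result.center_flowgrams,
        result.read_flow_lengths, policy, result.phase,
    ))

write_fasta(records, outdir / "denoised.fasta")
print(f"\nwrote {len(records)} denoised reads to {outdir / 'denoised.fasta'}")
# The miss TSVs histogram every (center, read) flow-value pair judged
# distinct — dense off-diagonal mass near the threshold suggests the
# denoising distance is too small for the dataset.
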