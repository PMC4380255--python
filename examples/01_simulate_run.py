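"""Simulate a small flow-space sequencing run with known ground truth.

Builds 60 reads from 3 reference sequences: each read is the reference
prefixed by its sample's mid tag and primer, turned into an ideal integer
flowgram over the TACG cycle, perturbed with homopolymer-dependent Gaussian
noise, and re-called into bases — so the reads carry realistic in/del
errors whose true origin is recorded in a truth table.
"""

from pathlib import Path

from ampliflow.synthgen import SimConfig, write_run

out = Path("example_output/sim")
cfg = SimConfig(seed=11, n_references=3, ref_length=240, reads_per_ref=20)
run = write_run(cfg, out)

print(f"wrote {run.n_reads} reads over {len(run.references)} references")
print(f"flow order {run.flow_order.chars} x {run.flow_order.num_flows} flows")
print(f"sff.txt dump : {run.sff_path}")
print(f"truth table  : {run.truth_path}")
print(f"sample sheet : {run.sample_sheet_path}")
print(f"references   : {run.refs_path}")
# The truth table maps every read id to its sample and source reference,
# which is what lets the later stages be scored without real data.
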