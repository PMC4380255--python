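"""Judge the denoising run by what it changed.

Flow-based sequencing errors are almost entirely homopolymer in/dels, so a
trustworthy denoiser should make few substitutions.  Each filtered read is
globally aligned to its denoised self and the differences classified; with
simulated data we can additionally verify that the in/del error rate
against the true references went down.  Run 01-03 first.
"""

from pathlib import Path

from ampliflow import error_rate_vs_refs, read_fasta, spectrum

pre = read_fasta(Path("example_output/filtered/filtered.fasta"))
post = read_fasta(Path("example_output/denoised/denoised.fasta"))

spec = spectrum(pre, post)
print("changes made by denoising:")
print(f"  insertions    {spec.insertions}")
print(f"  deletions     {spec.deletions}")
print(f"  substitutions {spec.substitutions}  (of which N conversions: {spec.n_conversions})")
print(f"  total         {spec.total}")

refs = Path("example_output/sim/refs.fasta")
for label, reads in (("filtered", pre), ("denoised", post)):
    res = error_rate_vs_refs(reads, refs)
    print(f"{label:9s} in/del error rate vs references: {res.rate:.6f} "
          f"({res.insertions}+{res.deletions} over {res.aligned_length} bases)")
# A substitution-light spectrum and a reduced error rate together indicate
# the distance setting removed sequencing error rather than real variation.
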