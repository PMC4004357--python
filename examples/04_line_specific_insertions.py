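"""Find de novo insertions by subtracting the parent line's call set.

A derivative line shares the parent's pre-existing insertions; calling both
and subtracting leaves the line-specific (de novo) events, the usual way
new transposition events are isolated from inherited copies.
"""

import tifind as tf

genome = tf.make_genome(1, [80_000], seed=30)
te = tf.random_te(length=400, seed=31)
sig = tf.signature_from_te(te)

sites = tf.choose_sites(genome, 5, tsd_len=5, seed=32)
parent_sites, all_sites = sites[:2], sites  # derivative adds 3 de novo
mut_parent, _ = tf.plant_insertions(genome, te, tsd_len=5,
                                    sites=parent_sites, seed=33)
mut_deriv, _ = tf.plant_insertions(genome, te, tsd_len=5,
                                   sites=all_sites, seed=33)

calls_parent = tf.run_extended(
    iter(tf.generate_reads(mut_parent, coverage=30.0, seed=34)), sig, genome)
calls_deriv = tf.run_extended(
    iter(tf.generate_reads(mut_deriv, coverage=30.0, seed=35)), sig, genome)

result = tf.diff_calls(calls_deriv, calls_parent)
common, deriv_only, parent_only = result.summary
print(f"common loci: {common}  derivative-specific: {deriv_only}  "
      f"parent-specific: {parent_only}")
for c in result.sample_specific:
    print(f"de novo  {c.chrom}:{c.span[0]}-{c.span[1]}  TSD={c.tsd_seq}  "
          f"{c.direction}")
# the derivative-specific list is exactly the three extra planted sites
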