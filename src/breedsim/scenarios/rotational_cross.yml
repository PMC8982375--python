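# Rotational crossbreeding among three cattle-like breeds.
# A base population is random-mated to build linkage disequilibrium,
# bottlenecked, and split into pure breeds A (small), B and C (large);
# the crossbred line then rotates the sire breed B -> A -> C.
case_study: rotational_cross
seed: 42
params:
  n_chr: 1
  n_loci: 100
  founder_n: 1500
  burn_in: 1000        # generations of random mating before the bottleneck
  bottleneck_n: 100
  post_bottleneck: 15
  purebred_gens: 10
  n_rotations: 3
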