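# S. cerevisiae preset: 31-nt windows, optimal feature subset and RBF-SVM
# hyperparameters for the S_628 benchmark training set.
species: yeast
training_set: S_628
xi: 15
recipe: [DC, PSNP, pseDNC]
kernel_scale: 0.25
box_constraint: 2
psednc:
  lambda: 2
  w: 0.5
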