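# M. musculus preset: 21-nt windows, optimal feature subset and RBF-SVM
# hyperparameters for the M_944 benchmark training set.
species: mouse
training_set: M_944
xi: 10
recipe: [PSNP, DC]
kernel_scale: 1
box_constraint: 2
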