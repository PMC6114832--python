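# H. sapiens preset: 21-nt windows, optimal feature subset and RBF-SVM
# hyperparameters for the H_990 benchmark training set.
species: human
training_set: H_990
xi: 10
recipe: [PSNP, DC]
kernel_scale: 2
box_constraint: 8
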