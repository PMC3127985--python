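ingredient,ahfs_class
alendronate,92:24
clodronate,92:24
etidronate,92:24
pamidronate,92:24
risedronate,92:24
zoledronic acid,92:24
salmon calcitonin,68:24
raloxifene,68:16
teriparatide,68:29
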