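# Curated panel of immune-related organs and tissues used for the
# target-organ localization network (one tissue per line; lines starting
# with '#' are ignored).
colon
small intestine
liver
colorectal adenocarcinoma
smooth muscle
bone marrow
thymus
lymph node
CD33+ myeloid
CD34+
721 B lymphoblasts
CD56+ NK
CD14+ monocytes
CD4+ T
CD8+ T
BDCA4+ DC
CD19+ B
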