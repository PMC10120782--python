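variable,level,count
age_group,<35,84
age_group,35-44,198
age_group,45-54,231
age_group,>=55,277
er,neg,287
er,pos,307
pr,neg,282
pr,pos,309
her2,neg,422
her2,pos,137
grade,1,38
grade,2,168
grade,3,474
size_cat,<2,23
size_cat,2-5,248
size_cat,>5,483
subtype,luminal A-like,166
subtype,luminal B-like,188
subtype,HER2-enriched,47
subtype,TNBC,154
menarche_cat,<15,185
menarche_cat,15,183
menarche_cat,16,151
menarche_cat,>=17,167
parity_status,nulliparous,71
parity_status,parous,719
n_children,1,88
n_children,2,125
n_children,3,136
n_children,4,123
n_children,>=5,247
afb_cat,<19,230
afb_cat,19-21,200
afb_cat,22-25,180
afb_cat,>=26,137
breastfeeding_cat,<13,240
breastfeeding_cat,13-18,415
breastfeeding_cat,>=19,97
body_size,slight,190
body_size,moderate,296
body_size,heavy,260
fhbc,no,726
fhbc,yes,55
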