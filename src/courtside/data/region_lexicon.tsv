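# Default keyword -> body-region lexicon for free-text injury notes.
# One mapping per line: lowercase keyword, a tab, then the region.
# Regions: groin/hip/thigh, knee, ankle, other.  Notes with no keyword hit
# map to "unknown".  Edit or replace this file to change the mapping; the
# assignment of Achilles-tendon keywords to "ankle" is a package convention
# (regional, not diagnosis-level, coding).
acl	knee
mcl	knee
pcl	knee
meniscus	knee
patella	knee
patellar	knee
knee	knee
groin	groin/hip/thigh
hip	groin/hip/thigh
hip flexor	groin/hip/thigh
thigh	groin/hip/thigh
hamstring	groin/hip/thigh
quad	groin/hip/thigh
quadriceps	groin/hip/thigh
adductor	groin/hip/thigh
ankle	ankle
achilles	ankle
back	other
shoulder	other
wrist	other
hand	other
elbow	other
head	other
concussion	other
illness	other
flu	other
calf	other
foot	other
toe	other
rib	other
neck	other
finger	other
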