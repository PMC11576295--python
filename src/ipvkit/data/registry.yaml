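# Default instrument registry: four flourishing questionnaires, 47 items.
# Item wording is not reproduced (copyright); items are identified as
# INSTRUMENT-SUBSCALE-index. `items` may be an integer count (ids are
# generated) or an explicit id list. `ranges` overrides the subscale-level
# `range` for individual item indices (needed for WBCF, whose items mix
# 5-, 4- and 11-point response formats).
MHC-SF:
  EWB: {items: 3, range: [0, 5]}
  SWB: {items: 5, range: [0, 5]}
  PWB: {items: 6, range: [0, 5]}
PERMA:
  P: {items: 3, range: [0, 10]}
  E: {items: 3, range: [0, 10]}
  R: {items: 3, range: [0, 10]}
  M: {items: 3, range: [0, 10]}
  A: {items: 3, range: [0, 10]}
FS:
  FS: {items: 8, range: [1, 7]}
WBCF:
  PC:
    items: 6
    range: [0, 4]
    # index 1: emotional stability, index 6: vitality (4-point);
    # index 4: positive emotions (11-point); index 2 is the negatively
    # worded self-esteem item.
    ranges: {1: [0, 3], 4: [0, 10], 6: [0, 3]}
    reverse: [2]
  PF:
    items: 4
    range: [0, 4]
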