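"""Private-attribute addressing and pixel burn-in, the two places PHI hides
from naive header scrubbers.

Private attributes live in odd groups behind a creator reservation; the
toolkit addresses them as (group, "CREATOR", byte) and resolves the block at
runtime.  Burned-in annotations are rendered glyph-by-glyph at the maximum
pixel value, so redaction checks can tell "text present" from "region
masked".
"""

import numpy as np

from deidbench import injector as inj
from deidbench import phantom_factory as pf
from deidbench.dicom_core import resolve_private
from deidbench.tags import parse_tag

row = pf.ManifestRow("PT", 1, 1, 1, 1, (("BREAST", 1),), (("GE MEDICAL SYSTEMS", 1),))
ds, _ = pf.build_dataset(pf.CompositionManifest(rows=(row,)), seed=2, matrix=128)
inst = ds.instances[0]

batch = parse_tag('(0009,"GEMS_PETD_01",37)')
print("before injection:", resolve_private(inst, batch))
inj.apply_set_tag(ds, inj.InjectionDirective(
    scope="Collection", selector="*", op="set_tag", tag=batch,
    params={"value": "BATCH 4410007", "phi_spans": ["BATCH 4410007"]},
))
el = resolve_private(inst, batch)
print("after injection: ", el.value, "| creator reserved at (0009,0010):",
      inst.get_value(parse_tag("(0009,0010)")))

before = inst.pixels.copy()
inj.apply_annotate_img(ds, inj.InjectionDirective(
    scope="Instance", selector=inst.instance_uid, op="annotate_img",
    params={"text": "ROGERS^BILLY\n19430722", "rect": [8, 8, 40, 120]},
))
after = inst.pixels
burned = int((after == 0xFFFF).sum())
untouched = bool(np.array_equal(after[40:, :], before[40:, :]))
print(f"burn-in: {burned} glyph pixels at max value; rows below rect untouched: {untouched}")
# A header-only de-identifier would leave both the private batch string and
# the burned-in name/birth date in place; the answer key checks both.
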