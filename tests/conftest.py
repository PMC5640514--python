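import numpy as np

from myonuc.mt import Microtubule


def straight_mt(length=5.0, l0=2.0):
    """A straight +x microtubule of given length with target segments l0."""
    n_full = int(length // l0)
    last = length - n_full * l0
    if last == 0:
        n_full -= 1
        last = l0
    xs = np.arange(n_full + 1) * l0
    verts = np.column_stack([np.append(xs, n_full * l0 + last),
                             np.zeros(n_full + 2)])
    return Microtubule(verts, segment_length_target=l0, last_segment=last)
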