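"""Small builders shared by the test modules."""

import numpy as np

from paleomito import Assembly, CircularSequence, Pileup


def toy_assembly_counts(count_rows, dels=None):
    """Assembly wrapping a hand-written pileup (rows of A,C,G,T counts)."""
    counts = np.asarray(count_rows, dtype=np.int32)
    length = len(counts)
    pileup = Pileup(length)
    pileup.counts += counts
    if dels is not None:
        pileup.deletions += np.asarray(dels, dtype=np.int32)
    return Assembly(
        bait_id="toy",
        mismatch_value=0.0,
        working_sequence=CircularSequence(id="toy", bases="A" * length),
        alignments=[],
        pileup=pileup,
        n_iterations=1,
        converged=True,
    )
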