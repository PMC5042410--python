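"""Shared fixtures: hand-computed hit sets and small synthetic genomes."""

import pytest

from phagesieve.blast_io import AlignmentHit


def make_hit(
    query_id="c1",
    subject_id="p1",
    pct_identity=98.0,
    aln_length=1000,
    q_start=1,
    q_end=1000,
    evalue=1e-10,
    **kw,
):
    defaults = dict(
        mismatches=0,
        gap_opens=0,
        s_start=1,
        s_end=q_end - q_start + 1,
        bit_score=1800.0,
    )
    defaults.update(kw)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=pct_identity,
        aln_length=aln_length,
        q_start=q_start,
        q_end=q_end,
        evalue=evalue,
        **defaults,
    )


@pytest.fixture
def worked_example_hits():
    """Two hits on a 2000 bp query: (id 90, al 1000, [1,1000]) and
    (id 70, al 500, [1501,2000]).  Identity term (90*1000 + 70*500)/1500
    = 83.33..., coverage 1500/2000 = 0.75, %ANI = 62.5 exactly."""
    return [
        make_hit(subject_id="p1", pct_identity=90.0, aln_length=1000,
                 q_start=1, q_end=1000),
        make_hit(subject_id="p2", pct_identity=70.0, aln_length=500,
                 q_start=1501, q_end=2000),
    ]
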