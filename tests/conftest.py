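import numpy as np
import pytest
from hypothesis import settings

from ancid import AlignmentHit, SequenceRecord
from ancid.presets import environmental_background, toy_database

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_refs():
    """The study's fixed 5-species reference database and taxonomy."""
    return toy_database()


@pytest.fixture(scope="session")
def env_background():
    return environmental_background()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def mixture(toy_refs):
    """5-species damaged mixture with precomputed hits, for stability tests."""
    from ancid.align import search
    from ancid.damage import SimConfig, SimSource, simulate_reads
    from ancid.presets import ENDOGENOUS_DAMAGE

    refs, taxmap = toy_refs
    fracs = (0.40, 0.25, 0.15, 0.12, 0.08)
    sim = SimConfig(
        sources=tuple(
            SimSource(tuple(refs[i : i + 1]), taxmap.species_of(refs[i].id),
                      f, ENDOGENOUS_DAMAGE)
            for i, f in enumerate(fracs)
        ),
        n_reads=3000, frag_len_mean=72.0, frag_len_sd=18.0, seed=21,
    )
    reads, _ = simulate_reads(sim)
    hits = search(reads, refs)
    return refs, taxmap, reads, hits


def make_hit(
    qid="r1",
    sid="MT001",
    pident=98.0,
    qstart=1,
    qend=50,
    qlen=50,
    sstart=101,
    send=150,
    alen=None,
    mismatches=1,
    gapopens=0,
    evalue=1e-20,
    bitscore=90.1,
    qaln=None,
    saln=None,
):
    return AlignmentHit(
        qid=qid,
        sid=sid,
        pident=pident,
        alen=alen if alen is not None else qend - qstart + 1,
        mismatches=mismatches,
        gapopens=gapopens,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        evalue=evalue,
        bitscore=bitscore,
        qlen=qlen,
        qaln=qaln,
        saln=saln,
    )


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def record_factory():
    return SequenceRecord
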