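"""Canonical synthetic study conditions used by the tests and the
reproduction script.

The toy study emulates a shotgun library from a degraded mammal sample:

* a 5-species mitochondrial-scale reference database (16 kb sequences,
  10% pairwise divergence; fixed seeds so the database is a constant of
  the study),
* an endogenous source with heavy terminal deamination (terminal
  C→T/G→A frequency 0.5 decaying inward at rate 0.25 per base —
  within the 2%–80% range observed across real degraded samples, at the
  damage level typical of the oldest ones, which are the motivating
  case for damage screening),
* a small in-database modern contaminant (2% of reads, undamaged),
  standing in for modern human/livestock carryover,
* the remainder drawn from a 100 kb "environmental" sequence absent
  from the database, standing in for the microbial background that
  dominates real libraries,
* lognormal fragment lengths, mean 72 bp / sd 18 bp (the midpoint of
  reported per-sample means, 46–93 bp), floor 30 bp, and a 0.2%
  uniform sequencing-error rate.
"""

from __future__ import annotations

from .damage import DamageModel, SimConfig, SimSource, simulate_references
from .seqio import SequenceRecord, TaxonomyMap

__all__ = ["toy_database", "toy_study_config", "ENDOGENOUS_DAMAGE"]

#: damage model of the endogenous source in the toy study
ENDOGENOUS_DAMAGE = DamageModel(d5=0.5, d3=0.5, lam=0.25)

_DB_SEED = 1
_ENV_SEED = 99


def toy_database(
    n_species: int = 5, length: int = 16000, divergence: float = 0.1
) -> tuple[list[SequenceRecord], TaxonomyMap]:
    """The study's fixed reference database (seeded constants)."""
    return simulate_references(n_species, length, divergence, seed=_DB_SEED)


def environmental_background(length: int = 100000) -> list[SequenceRecord]:
    """Off-database contaminant source (never in the taxonomy map)."""
    records, _ = simulate_references(1, length, 0.25, seed=_ENV_SEED, prefix="ENV")
    return records


def toy_study_config(
    endogenous_fraction: float,
    n_reads: int = 10000,
    seed: int = 0,
    contaminant_fraction: float = 0.02,
    damage: DamageModel = ENDOGENOUS_DAMAGE,
) -> tuple[list[SequenceRecord], TaxonomyMap, SimConfig]:
    """Assemble the canonical mixture for one simulated sample.

    The endogenous source is the database's first species; the
    in-database contaminant is the second; everything else is
    environmental background. Returns (database, taxonomy, sim config).
    """
    refs, taxmap = toy_database()
    env = environmental_background()
    env_fraction = round(1.0 - endogenous_fraction - contaminant_fraction, 9)
    if env_fraction < 0:
        raise ValueError("endogenous + contaminant fractions exceed 1")
    cfg = SimConfig(
        sources=(
            SimSource(tuple(refs[0:1]), taxmap.species_of(refs[0].id),
                      endogenous_fraction, damage),
            SimSource(tuple(refs[1:2]), taxmap.species_of(refs[1].id),
                      contaminant_fraction, None),
            SimSource(tuple(env), "environment", env_fraction, None),
        ),
        n_reads=n_reads,
        frag_len_mean=72.0,
        frag_len_sd=18.0,
        seed=seed,
    )
    return refs, taxmap, cfg
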