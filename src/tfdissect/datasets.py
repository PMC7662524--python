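"""Bundled reference measurements for the TTHB099 study system.

Small published tables used as analysis inputs and test fixtures:

- consensus/mutant BLI kinetics (kon, koff, KD, R²) for the TTHB099
  16-mer consensus TGTATTCTAGAATACA, its single-point mutants, and the
  cAMP-supplemented control;
- the 25 top-scoring genome-mapped consensus sites in *Thermus
  thermophilus* HB8 with TSS-relative locations and operon positions;
- BLI kinetics of TTHB099 against the mapped promoter-region sites
  (one probe, TTHA0374, shows no detectable binding and carries no
  rate entries).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: TTHB099 consensus binding site (palindromic 16-mer)
CONSENSUS = "TGTATTCTAGAATACA"

#: analyte concentrations (molar) used in the 4-point BLI titrations
BLI_CONCENTRATIONS = (17e-9, 50e-9, 150e-9, 450e-9)


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("tfdissect.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def consensus_mutant_kinetics() -> pd.DataFrame:
    """BLI rate constants for the consensus (wt), eight half-site point
    mutants m1–m8, and the consensus in the presence of cAMP."""
    return _load("tthb099_consensus_mutant_kinetics.tsv")


def genome_sites() -> pd.DataFrame:
    """Top 25 genome-mapped consensus sites with per-gene TSS-relative
    location (loc) and operon position labels."""
    return _load("tthb099_genome_sites.tsv")


def promoter_site_kinetics() -> pd.DataFrame:
    """BLI rate constants for the nine unique promoter-region probes;
    rows without rates indicate no detectable binding."""
    return _load("tthb099_promoter_site_kinetics.tsv")
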