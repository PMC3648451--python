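"""Species codes and the stochastic rule-probability table.

Every molecular interaction in the intracellular model is gated by a single
uniform draw against a fixed probability; :class:`RuleTable` holds those
probabilities. The defaults are the published parameter set of the competence
switch model (binding affinities, transcription/translation rates, mRNA decay
and protease processivity expressed as per-tick success probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

# Species codes (shared with the jitted kernel).
COMK, COMS, COMX, DEGU, MECA, CLPCP, RIBOSOME, REPRESSOR, MRNA_COMK, MRNA_COMS = range(10)

SPECIES_NAMES = {
    COMK: "ComK",
    COMS: "ComS",
    COMX: "ComX",
    DEGU: "DegU",
    MECA: "MecA",
    CLPCP: "ClpCP",
    RIBOSOME: "Ribosome",
    REPRESSOR: "Repressor",
    MRNA_COMK: "mRNA_comK",
    MRNA_COMS: "mRNA_comS",
}

# Promoter gene identities.
GENE_COMK, GENE_COMS = 0, 1

# Complex kinds.
COMK_DIMER, CLPCP_MECA, CLPCP_MECA_COMK, CLPCP_MECA_COMS, RIBOSOME_MRNA = range(5)

COMPLEX_NAMES = {
    COMK_DIMER: "ComK_dimer",
    CLPCP_MECA: "ClpCP_MecA",
    CLPCP_MECA_COMK: "ClpCP_MecA_ComK",
    CLPCP_MECA_COMS: "ClpCP_MecA_ComS",
    RIBOSOME_MRNA: "Ribosome_mRNA",
}


@dataclass
class RuleTable:
    """Per-tick rule execution probabilities (the rho of the bind rule).

    bind_* probabilities apply when the two partners occupy adjacent lattice
    sites; transcription_* depend on what is bound at the promoter;
    dissociation_* are per-tick release probabilities of promoter-bound
    repressor/DegU.
    """

    bind_repressor_promoter: float = 0.5
    bind_degu_promoter: float = 0.5
    bind_comx_promoter: float = 0.5
    bind_comk_dimer_promoter: float = 0.5
    # with DegU already at the comK promoter, dimer binding is stimulated
    bind_comk_dimer_promoter_degu: float = 0.8
    bind_comk_comk: float = 0.8
    bind_ribosome_mrna: float = 0.9
    bind_protease_comk: float = 0.6
    # ComS out-competes ComK for the MecA adapter
    bind_protease_coms: float = 0.7
    bind_clpcp_meca: float = 0.5
    transcription_bare: float = 1e-4
    transcription_dimer: float = 1e-3
    transcription_tetramer: float = 0.5
    transcription_comx: float = 0.5
    translation: float = 0.5
    mrna_death: float = 1e-4
    protease_degradation: float = 0.5
    dissociation_repressor: float = 1e-4
    dissociation_degu: float = 1e-4

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= float(v) <= 1.0):
                raise ValueError(f"{f.name}={v!r} is not a probability")

    def to_array(self) -> np.ndarray:
        """Pack into the float64 vector consumed by the jitted kernel.

        The field order of this dataclass *is* the kernel's index order.
        """
        return np.array(
            [float(getattr(self, f.name)) for f in fields(self)], dtype=np.float64
        )

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "RuleTable":
        return cls(**d)
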