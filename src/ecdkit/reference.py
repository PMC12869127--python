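"""Literature reference values for the GHRP peptide family.

Sequences and average molar masses of the growth hormone-releasing
peptides handled by this package, and the reported backbone phi/psi
torsion tables of the five GHRP-5 conformers identified as dominant in
aqueous solution (aq-I, aq-II) and in the presence of SDS micelles
(mic-I, mic-II, mic-III).  These printed values serve as validation
inputs; the original Cartesian geometries are not redistributed here, so
geometry-level checks use synthetic backbones reconstructed from the
torsion tables (see :mod:`ecdkit.synth`).
"""

from __future__ import annotations

#: sequence strings as commonly written (D/L prefixes, trailing NH2)
GHRP_SEQUENCES: dict[str, str] = {
    "GHRP-3": "α-Methyl-L-Ala-D-Trp-D-Pro-D-Ile-L-Arg-NH2",
    "GHRP-4": "D-Trp-L-Ala-L-Trp-D-Phe-NH2",
    "GHRP-5": "L-Tyr-D-Trp-L-Ala-L-Trp-D-Phe-NH2",
    "GHRP-6": "L-His-D-Trp-L-Ala-L-Trp-D-Phe-L-Lys-NH2",
    # canonical ipamorelin composition; the naphthyl-alanine is written 2Nal
    "ipamorelin": "Aib-L-His-L-2Nal-D-Phe-L-Lys-NH2",
}

#: reported average molar masses (g/mol) for the sequences above
REPORTED_AVERAGE_MASS: dict[str, float] = {
    "GHRP-3": 654.8,
    "GHRP-4": 607.7,
    "GHRP-5": 770.9,
    "GHRP-6": 873.0,
    "ipamorelin": 711.9,
}

#: reported (phi, psi) tables (deg) of the five dominant GHRP-5 conformers;
#: four rows per conformer, numbered from the tyrosine (N-terminal) end,
#: row k holding the angles of residue k+1 with the final psi closed by the
#: C-terminal amide nitrogen
GHRP5_CONFORMER_TORSIONS: dict[str, list[tuple[float, float]]] = {
    "aq-I": [(46.2, -131.3), (-95.9, 19.6), (125.8, 41.5), (-91.0, 76.7)],
    "aq-II": [(108.5, -148.6), (-80.4, 75.8), (77.5, -74.8), (-114.4, -178.0)],
    "mic-I": [(78.5, -72.8), (-66.8, 94.2), (48.2, -146.1), (-135.6, 105.3)],
    "mic-II": [(45.9, -132.6), (-101.2, 30.0), (112.7, 44.3), (-109.5, 94.2)],
    "mic-III": [(77.8, -70.4), (-65.7, 92.9), (47.0, -140.6), (-167.8, 161.7)],
}

#: reported optimal conformer abundances (percent) from the shape fit of the
#: GHRP-5 spectra: two conformers in water, three with SDS micelles
REPORTED_ABUNDANCES_PERCENT: dict[str, dict[str, float]] = {
    "aqueous": {"aq-I": 80.0, "aq-II": 17.0},
    "micelle": {"mic-I": 65.0, "mic-II": 25.0, "mic-III": 8.0},
}
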