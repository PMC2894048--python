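# Column map for curated entry tables (file column -> canonical column).
# The bundled synthetic_database.tsv already uses canonical names, so this map
# is the identity; edit the keys to ingest a table with different headers.
#
# Canonical columns and units:
#   protein                    text label of the aggregating polypeptide
#   protein_length             residues
#   protein_net_charge         elementary charges at pH 7.5
#   protein_lys_arg            Lys + Arg residue count
#   folding_status             globular | natively_unfolded
#   disease_related            True | False
#   gag                        text label of the glycosaminoglycan
#   sulfates_per_disaccharide  sulfate groups per disaccharide unit (P_S)
#   charges_per_disaccharide   negative charges per disaccharide unit
#   uronic_acid                glucuronic | iduronic | none
#   sulfation_position         N | O | mixed | none
#   gag_molecular_weight       Da (optional, empty cell = absent)
#   solute_molarity            total buffer solute molarity, mM (P_B)
#   protein_conc               protein concentration, uM
#   gag_conc                   GAG concentration, uM
#   protein_gag_molar_ratio    protein_conc / gag_conc, dimensionless (P_MR)
#   pH, temperature            solution pH and temperature (deg C)
#   buffer                     free-text buffer description
#   t_half_no_gag              aggregation half-time without GAG
#   t_half_with_gag            aggregation half-time with GAG (same unit)
#   time_unit                  s | min | h | d (normalized to hours at load)
#   G                          ln(t_half_no_gag / t_half_with_gag)
#   source                     citation text
protein: protein
protein_length: protein_length
protein_net_charge: protein_net_charge
protein_lys_arg: protein_lys_arg
folding_status: folding_status
disease_related: disease_related
gag: gag
sulfates_per_disaccharide: sulfates_per_disaccharide
charges_per_disaccharide: charges_per_disaccharide
uronic_acid: uronic_acid
sulfation_position: sulfation_position
gag_molecular_weight: gag_molecular_weight
solute_molarity: solute_molarity
protein_conc: protein_conc
gag_conc: gag_conc
protein_gag_molar_ratio: protein_gag_molar_ratio
pH: pH
temperature: temperature
buffer: buffer
t_half_no_gag: t_half_no_gag
t_half_with_gag: t_half_with_gag
time_unit: time_unit
G: G
source: source
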