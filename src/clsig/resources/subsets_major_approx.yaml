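# Best-effort curated definitions of the 19 major CLL stereotyped subsets.
#
# PROVENANCE / CAVEATS
# - Core features (IGHV clan, mutational status, CDR3 length, hallmark V
#   genes, light-chain bias) are approximations compiled from the general CLL
#   stereotypy literature; entries marked "approx" are uncertain.
# - reference_cdr3s are SYNTHETIC placeholder exemplars matching the stated
#   length only: the true reference CDR3 sequences and motif patterns live in
#   curated external resources and are not redistributed here. Patterns are
#   therefore permissive (all-x). Replace this file with a properly curated
#   one for real-data analysis.
# - cll_reference_freq values are approximate relative frequencies among
#   major-subset CLL stereotyped clones (they sum to 1 over this file).
# Tests and simulations in this package use subsets_synthetic.yaml instead.
subsets:
  - subset_id: "#1"    # clan I, unmutated, 13 aa, IGK-biased
    clan: I
    core_mut_status: U
    cdr3_length: 13
    reference_cdr3s: [ARDQNAMDYWYFD]        # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-2, IGHV1-3, IGHV1-18, IGHV5-51, IGHV7-4-1]
    predominant_v_gene: IGHV1-2
    cll_reference_freq: 0.170
    light_chain_bias: KAPPA
  - subset_id: "#2"    # IGHV3-21, borderline mutational status, 9 aa, IGL
    clan: III
    core_mut_status: EITHER
    cdr3_length: 9
    reference_cdr3s: [ARDANGMDV]            # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV3-21, IGHV3-48]
    predominant_v_gene: IGHV3-21
    cll_reference_freq: 0.190
    light_chain_bias: LAMBDA
  - subset_id: "#3"    # IGHV1-69, unmutated, long CDR3 (approx 22 aa)
    clan: I
    core_mut_status: U
    cdr3_length: 22
    reference_cdr3s: [ARGGIYDSSGYYAREYGMDVWG]    # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-69, IGHV1-2]
    predominant_v_gene: IGHV1-69
    cll_reference_freq: 0.050
    light_chain_bias: NONE
  - subset_id: "#4"    # IGHV4-34, mutated, 20 aa
    clan: II
    core_mut_status: M
    cdr3_length: 20
    reference_cdr3s: [ARGYGDYVWGSYRLTGGMDV]  # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV4-34]
    predominant_v_gene: IGHV4-34
    cll_reference_freq: 0.090
    light_chain_bias: KAPPA                  # approx
  - subset_id: "#5"    # approx: clan I, unmutated
    clan: I
    core_mut_status: U
    cdr3_length: 20
    reference_cdr3s: [ARRGGYYDTSGYSPNWFDPW]  # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-69, IGHV1-2, IGHV1-3]
    predominant_v_gene: IGHV1-69
    cll_reference_freq: 0.030
    light_chain_bias: NONE
  - subset_id: "#6"    # IGHV1-69, unmutated, 21 aa, IGK
    clan: I
    core_mut_status: U
    cdr3_length: 21
    reference_cdr3s: [ARGGGYSSSWYDYYYGMDVWG]  # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-69]
    predominant_v_gene: IGHV1-69
    cll_reference_freq: 0.050
    light_chain_bias: KAPPA
  - subset_id: "#7H"   # approx: clan I, unmutated
    clan: I
    core_mut_status: U
    cdr3_length: 13
    reference_cdr3s: [ARVGSYYGMDVWG]          # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-69, IGHV1-2]
    predominant_v_gene: IGHV1-69
    cll_reference_freq: 0.030
    light_chain_bias: NONE
  - subset_id: "#8"    # IGHV4-39, unmutated, 19 aa, IGK
    clan: II
    core_mut_status: U
    cdr3_length: 19
    reference_cdr3s: [ARHRSGYSSGWYYEGMDVW]    # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV4-39]
    predominant_v_gene: IGHV4-39
    cll_reference_freq: 0.060
    light_chain_bias: KAPPA
  - subset_id: "#9"    # approx: clan I, unmutated, IGK
    clan: I
    core_mut_status: U
    cdr3_length: 14
    reference_cdr3s: [ARDPSNYYDRSMDV]         # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-2, IGHV1-3]
    predominant_v_gene: IGHV1-2
    cll_reference_freq: 0.030
    light_chain_bias: KAPPA
  - subset_id: "#12"   # approx: clan I, unmutated
    clan: I
    core_mut_status: U
    cdr3_length: 16
    reference_cdr3s: [ARDKGSYYYDSSGYYH]       # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-69, IGHV1-2]
    predominant_v_gene: IGHV1-69
    cll_reference_freq: 0.025
    light_chain_bias: NONE
  - subset_id: "#14"   # mutated, clan II (IGHV4-4 predominant)
    clan: II
    core_mut_status: M
    cdr3_length: 15
    reference_cdr3s: [ARGQWLEGDYYYGMD]        # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV4-4, IGHV4-34]
    predominant_v_gene: IGHV4-4
    cll_reference_freq: 0.020
    light_chain_bias: NONE
  - subset_id: "#16"   # approx: clan II, mutated
    clan: II
    core_mut_status: M
    cdr3_length: 24
    reference_cdr3s: [ARDGSGSYYWGSYRPKNYYYYYMD]  # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV4-34, IGHV4-39]
    predominant_v_gene: IGHV4-34
    cll_reference_freq: 0.020
    light_chain_bias: NONE
  - subset_id: "#28A"  # approx: clan I, mutated
    clan: I
    core_mut_status: M
    cdr3_length: 12
    reference_cdr3s: [ARDLYYYGSGSY]           # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-2, IGHV1-18]
    predominant_v_gene: IGHV1-2
    cll_reference_freq: 0.020
    light_chain_bias: NONE
  - subset_id: "#31"   # approx: clan I, unmutated
    clan: I
    core_mut_status: U
    cdr3_length: 19
    reference_cdr3s: [ARDGGYCSSTSCYRGGMDV]    # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-69, IGHV5-51]
    predominant_v_gene: IGHV1-69
    cll_reference_freq: 0.020
    light_chain_bias: NONE
  - subset_id: "#59"   # approx: clan III, unmutated
    clan: III
    core_mut_status: U
    cdr3_length: 18
    reference_cdr3s: [ARDRSTVTTPFDYWGQGT]     # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV3-21, IGHV3-48]
    predominant_v_gene: IGHV3-21
    cll_reference_freq: 0.020
    light_chain_bias: NONE
  - subset_id: "#64B"  # approx: clan I, unmutated, IGK-biased
    clan: I
    core_mut_status: U
    cdr3_length: 14
    reference_cdr3s: [ARDSNYDFWSGYYT]         # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV1-69, IGHV1-2, IGHV1-18]
    predominant_v_gene: IGHV1-69
    cll_reference_freq: 0.015
    light_chain_bias: KAPPA
  - subset_id: "#77"   # approx: clan III, mutated
    clan: III
    core_mut_status: M
    cdr3_length: 13
    reference_cdr3s: [ARDIVLMVYAIFD]          # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV3-23, IGHV3-7]
    predominant_v_gene: IGHV3-23
    cll_reference_freq: 0.015
    light_chain_bias: NONE
  - subset_id: "#99"   # approx: clan III, mutated, IGL
    clan: III
    core_mut_status: M
    cdr3_length: 11
    reference_cdr3s: [ARDLGVYYYGM]            # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV3-7, IGHV3-23]
    predominant_v_gene: IGHV3-7
    cll_reference_freq: 0.020
    light_chain_bias: LAMBDA
  - subset_id: "#201"  # approx: clan II, mutated
    clan: II
    core_mut_status: M
    cdr3_length: 17
    reference_cdr3s: [ARGDYDYVWGSYRYTHH]      # synthetic exemplar
    pattern: {offset: 0, motif: [x]}
    typical_v_genes: [IGHV4-34, IGHV4-4]
    predominant_v_gene: IGHV4-34
    cll_reference_freq: 0.015
    light_chain_bias: NONE
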