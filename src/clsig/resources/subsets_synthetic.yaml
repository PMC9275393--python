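# Fully synthetic stereotyped-subset definitions for tests and
# simulations: every code path (clans, statuses, lengths, patterns,
# typical/predominant genes, light-chain bias) is exercised.
subsets:
  - subset_id: "T01"
    clan: I
    core_mut_status: U
    cdr3_length: 9
    reference_cdr3s: [ARGAMSYLV, ARCAMSWMA, ARCAMNYLA]
    pattern: {offset: 2, motif: [x, aliphatic, aliphatic, polar]}
    typical_v_genes: [IGHV1-2, IGHV7-4-1]
    predominant_v_gene: IGHV7-4-1
    cll_reference_freq: 0.19
    light_chain_bias: KAPPA
  - subset_id: "T02"
    clan: II
    core_mut_status: M
    cdr3_length: 11
    reference_cdr3s: [ARITIAWFDPF, VRITIMWFDCF, ARITIAFFEPW]
    pattern: {offset: 5, motif: [aliphatic, aromatic, aromatic, negative]}
    typical_v_genes: [IGHV2-5, IGHV4-34]
    predominant_v_gene: IGHV4-34
    cll_reference_freq: 0.17
    light_chain_bias: LAMBDA
  - subset_id: "T03"
    clan: III
    core_mut_status: EITHER
    cdr3_length: 12
    reference_cdr3s: [ARVEQCQHKRKT, ARLENPQHRRKT, IRVESGSHKRKT]
    pattern: {offset: 3, motif: [x, x, special]}
    typical_v_genes: [IGHV3-23, IGHV3-48]
    predominant_v_gene: IGHV3-23
    cll_reference_freq: 0.09
    light_chain_bias: NONE
  - subset_id: "T04"
    clan: I
    core_mut_status: U
    cdr3_length: 13
    reference_cdr3s: [ARKKVYYSMMYGH, ARHKMYWSMMYGH, ARHKVYFNIMYGH]
    pattern: {offset: 2, motif: [positive, positive, aliphatic]}
    typical_v_genes: [IGHV1-69, IGHV5-51, IGHV7-4-1]
    predominant_v_gene: IGHV5-51
    cll_reference_freq: 0.08
    light_chain_bias: KAPPA
  - subset_id: "T05"
    clan: II
    core_mut_status: M
    cdr3_length: 13
    reference_cdr3s: [ARWYNQGTQWGSL, ARWYSQPTQWGSL]
    pattern: {offset: 3, motif: [aromatic, polar, x, special]}
    typical_v_genes: [IGHV2-5, IGHV4-39, IGHV6-1]
    predominant_v_gene: IGHV4-39
    cll_reference_freq: 0.07
    light_chain_bias: LAMBDA
  - subset_id: "T06"
    clan: III
    core_mut_status: EITHER
    cdr3_length: 14
    reference_cdr3s: [ARCYLGMSHACVDP, LRCYLGISHIGVDP]
    pattern: {offset: 3, motif: [x, aliphatic, x]}
    typical_v_genes: [IGHV3-21, IGHV3-48]
    predominant_v_gene: IGHV3-21
    cll_reference_freq: 0.06
    light_chain_bias: NONE
  - subset_id: "T07"
    clan: I
    core_mut_status: U
    cdr3_length: 15
    reference_cdr3s: [ARHKKNSLTMGFHNF, ARHKKQSLTAGYHNF, IRHKKNNLTMGFHNY]
    pattern: {offset: 2, motif: [positive, x, x]}
    typical_v_genes: [IGHV1-2, IGHV5-51]
    predominant_v_gene: IGHV1-2
    cll_reference_freq: 0.06
    light_chain_bias: KAPPA
  - subset_id: "T08"
    clan: II
    core_mut_status: M
    cdr3_length: 15
    reference_cdr3s: [ARRPLFCNFNQTLAG, ARHPLFPNYNQTLAG, ARRCLFCNFNQTLVG]
    pattern: {offset: 6, motif: [special, polar, aromatic, polar]}
    typical_v_genes: [IGHV2-5, IGHV4-34, IGHV6-1]
    predominant_v_gene: IGHV4-34
    cll_reference_freq: 0.05
    light_chain_bias: LAMBDA
  - subset_id: "T09"
    clan: III
    core_mut_status: EITHER
    cdr3_length: 16
    reference_cdr3s: [ARPHTCVARHIAREQR, ARPRTGVARHMAHEQR, ARPHTCVARHVIREQR]
    pattern: {offset: 6, motif: [x, x, positive]}
    typical_v_genes: [IGHV3-21, IGHV3-23, IGHV3-48]
    predominant_v_gene: IGHV3-48
    cll_reference_freq: 0.05
    light_chain_bias: NONE
  - subset_id: "T10"
    clan: I
    core_mut_status: U
    cdr3_length: 17
    reference_cdr3s: [ARCVKMEPEGRCKNDGH, LRPVKMEPEGRPKNDGR, ARPVKMEPEPRCKNDGR]
    pattern: {offset: 9, motif: [special, positive, special, positive]}
    typical_v_genes: [IGHV1-2, IGHV1-69, IGHV7-4-1]
    predominant_v_gene: IGHV1-69
    cll_reference_freq: 0.04
    light_chain_bias: KAPPA
  - subset_id: "T11"
    clan: II
    core_mut_status: M
    cdr3_length: 18
    reference_cdr3s: [ARKKWCSVQIEQLDIYGE, ARKKWCSVQIEQLDIWGD, ARKRWCTVQIEQLDIYGE]
    pattern: {offset: 9, motif: [aliphatic, negative, polar, aliphatic]}
    typical_v_genes: [IGHV4-34, IGHV4-39, IGHV6-1]
    predominant_v_gene: IGHV6-1
    cll_reference_freq: 0.03
    light_chain_bias: LAMBDA
  - subset_id: "T12"
    clan: III
    core_mut_status: EITHER
    cdr3_length: 18
    reference_cdr3s: [ARWQVVSMCAFKRLAFYY, ARWQVVSMCAYRRLMWYY]
    pattern: {offset: 6, motif: [polar, aliphatic, special]}
    typical_v_genes: [IGHV3-21, IGHV3-7]
    predominant_v_gene: IGHV3-21
    cll_reference_freq: 0.03
    light_chain_bias: NONE
  - subset_id: "T13"
    clan: I
    core_mut_status: U
    cdr3_length: 19
    reference_cdr3s: [ARISDHEHQAHAYRFECLS, ARIQEKEHSAHAYRFECLS, VRASEHEHQAHAYRFECLS]
    pattern: {offset: 4, motif: [negative, x, negative, positive]}
    typical_v_genes: [IGHV1-69, IGHV5-51]
    predominant_v_gene: IGHV5-51
    cll_reference_freq: 0.02
    light_chain_bias: KAPPA
  - subset_id: "T14"
    clan: II
    core_mut_status: M
    cdr3_length: 20
    reference_cdr3s: [ARWDYPYIYNCKDWHFNKCT, ARWDYPYLYNPKDWHFNKGN, ARWDYPYIYTGKDWRFNKCT]
    pattern: {offset: 7, motif: [aliphatic, x, polar]}
    typical_v_genes: [IGHV2-5, IGHV4-39, IGHV6-1]
    predominant_v_gene: IGHV2-5
    cll_reference_freq: 0.02
    light_chain_bias: LAMBDA
  - subset_id: "T15"
    clan: III
    core_mut_status: EITHER
    cdr3_length: 21
    reference_cdr3s: [ARIGETPEQKCKEFVRDVNVR, ARIGENPEQKGKEFIRDVNVR]
    pattern: {offset: 15, motif: [positive, negative, aliphatic]}
    typical_v_genes: [IGHV3-21, IGHV3-48, IGHV3-7]
    predominant_v_gene: IGHV3-48
    cll_reference_freq: 0.01
    light_chain_bias: NONE
  - subset_id: "T16"
    clan: I
    core_mut_status: U
    cdr3_length: 10
    reference_cdr3s: [ARIDIDEYCL, AKIEIEEFCL, AKIEIDEYCL]
    pattern: {offset: 2, motif: [aliphatic, negative, aliphatic]}
    typical_v_genes: [IGHV1-2, IGHV1-69, IGHV5-51]
    predominant_v_gene: IGHV1-2
    cll_reference_freq: 0.01
    light_chain_bias: KAPPA
  - subset_id: "T17"
    clan: II
    core_mut_status: M
    cdr3_length: 12
    reference_cdr3s: [ARTTRILTETWQ, IRTTKILTETYQ]
    pattern: {offset: 5, motif: [x, aliphatic, polar, negative]}
    typical_v_genes: [IGHV2-5, IGHV4-34, IGHV4-39]
    predominant_v_gene: IGHV2-5
    cll_reference_freq: 0.01
    light_chain_bias: LAMBDA
  - subset_id: "T18"
    clan: III
    core_mut_status: EITHER
    cdr3_length: 14
    reference_cdr3s: [ARVCILSDKESPLI, ARVPIMSEKEQPLI]
    pattern: {offset: 2, motif: [aliphatic, special, x]}
    typical_v_genes: [IGHV3-23, IGHV3-48]
    predominant_v_gene: IGHV3-48
    cll_reference_freq: 0.005
    light_chain_bias: NONE
  - subset_id: "T19"
    clan: I
    core_mut_status: U
    cdr3_length: 16
    reference_cdr3s: [ARAYKGVRRGYLMSQE, ARAYKPVRRGFLMQQE]
    pattern: {offset: 7, motif: [positive, positive, special]}
    typical_v_genes: [IGHV1-2, IGHV1-69, IGHV7-4-1]
    predominant_v_gene: IGHV1-69
    cll_reference_freq: 0.005
    light_chain_bias: KAPPA
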