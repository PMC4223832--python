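# Cas operon subtype signatures (set-based, editable).
#
# A cluster is classified by the highest-priority signature whose required
# gene set is contained in the cluster and whose forbidden set is disjoint
# from it.  Clusters lacking cas3 are never classified (type I systems are
# defined by cas3).  Gene names are matched after alias normalization
# (see aliases.yaml).
signatures:
  - subtype: I-E
    priority: 60
    required: [cas3, cse1, cse2]
    optional: [cas7, cas5, cas6, cas1, cas2]
    forbidden: []
  - subtype: I-C
    priority: 50
    required: [cas3, cas8c]
    optional: [cas7, cas5, cas4, cas1, cas2]
    forbidden: []
  - subtype: I-B
    priority: 40
    # in this genus the canonical cas8b position is occupied by a larger
    # cst1-related gene
    required: [cas3, cst1]
    optional: [cas7, cas5, cas6, cas4, cas1, cas2]
    forbidden: []
  - subtype: I-U_csb3
    priority: 30
    required: [cas3, csb3]
    optional: [csb1, csb2, cas1, cas2]
    forbidden: []
  - subtype: I-U_csx17
    priority: 20
    required: [cas3, csx17]
    optional: [csb1, csb2]
    forbidden: [cas1]
  - subtype: I-U_Sa
    priority: 10
    required: [cas3, csb1, csb2]
    optional: [cas2]
    forbidden: [csb3, csx17, cas1]
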