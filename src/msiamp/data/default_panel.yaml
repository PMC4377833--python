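name: colorectal-msi-5
loci:
  - name: BAT25
    chromosome_label: 4q12
    coordinates_label: 55598151-55598274
    repeat_class: mono
    forward_primer: TCGCCTCCAAGAATGTAAGT
    reverse_primer: TCTGCATTTTAACTATGGCTC
    reference_amplicon_length: 123
    reference_modal_length: 123
  - name: BAT26
    chromosome_label: 2p
    coordinates_label: 47641487-47641608
    repeat_class: mono
    forward_primer: TGACTACTTTTGACTTCAGCC
    reverse_primer: AACCATTCAACATTTTTAACCC
    reference_amplicon_length: 121
    reference_modal_length: 121
  - name: BAT34c4
    chromosome_label: 17p13.1
    coordinates_label: 7572124-7572254
    repeat_class: mono
    forward_primer: ACCCTGGAGGATTTCATCTC
    reverse_primer: AACAAAGCGAGACCCAGTCT
    reference_amplicon_length: 130
  - name: D18S55
    chromosome_label: 18q22.1
    coordinates_label: 61873501-61873648
    repeat_class: di
    forward_primer: GGGAAGTCAAATGCAAATC
    reverse_primer: AGCTTCTGAGTAATCTTATGCTGTG
    reference_amplicon_length: 147
  - name: D5S346
    chromosome_label: 5q22.2
    coordinates_label: 112213624-112213748
    repeat_class: di
    forward_primer: ACTCACTCTAGTGATAAATCGGG
    reverse_primer: AGCAGATAAGACAGTATTACTAGTT
    reference_amplicon_length: 124
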