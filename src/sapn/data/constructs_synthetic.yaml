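# Synthetic reconstruction of the SAPN construct family.
#
# The experimentally studied sequences are not available in machine-readable
# form; these sequences are a synthetic stand-in engineered to satisfy every
# documented constraint: the 36-residue mini construct with residue
# identities E7, T15, G19 (linker hinge glycine), S23, E27, R30, E34 and an
# overall charge of -2 after the S23T mutation; a terminal arginine placed
# before the engineered stop codon; 2HR/2.5HR/3HR differing only by the
# trimer truncation length (2.0 / 2.5 / 3.0 heptad repeats); and ProtParam
# average molecular weights of 9805.7 Da (2.5HR) and 10251.3 Da (3HR).
# They are NOT the experimental sequences.
#
# Ranges are 1-based inclusive [start, end].

mini:
  # peptide 1, the parent of the eleven simulated mini constructs
  - name: peptide-1
    sequence: WKALKAELWQALAATLQSGSELSAIEELARILDELR
    pentamer: [1, 13]
    linker: [14, 20]
    trimer: [21, 36]

# peptides 2..11: point mutations on peptide 1, slash-joined notation
mini_mutants:
  peptide-2: S23T
  peptide-3: T15C/S23C
  peptide-4: S23N
  peptide-5: S23T/E7A
  peptide-6: T15C/S23C/E7A
  peptide-7: S23T/R30E
  peptide-8: T15C/S23C/R30E
  peptide-9: E7A
  peptide-10: R30E
  peptide-11: E7R/E27D

full_length:
  # His-tagged expression constructs; trimer truncated at 2, 2.5, 3 heptads
  - name: 2HR
    sequence: MGSSHHHHHHSSGLVPRGWKQLEDDWAQLEKDWSQLEAEWKDLEAQWAELEKSWSSSSSTATLQSGSIAALEQKIEELKARR
    pentamer: [19, 60]
    linker: [61, 67]
    trimer: [68, 82]
  - name: 2.5HR
    sequence: MGSSHHHHHHSSGLVPRGWKQLEDDWAQLEKDWSQLEAEWKDLEAQWAELEKSWSSSSSTATLQSGSIAALEQKIEELKARISADR
    pentamer: [19, 60]
    linker: [61, 67]
    trimer: [68, 86]
  - name: 3HR
    sequence: MGSSHHHHHHSSGLVPRGWKQLEDDWAQLEKDWSQLEAEWKDLEAQWAELEKSWSSSSSTATLQSGSIAALEQKIEELKARISADKMWR
    pentamer: [19, 60]
    linker: [61, 67]
    trimer: [68, 89]
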