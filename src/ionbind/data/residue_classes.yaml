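# Default physicochemical classifications of the 20 canonical amino acids.
# Both tables are editable: pass an alternative file to
# ionbind.discretizers.load_residue_classes to swap schemes without code
# changes (e.g. for sensitivity analysis).
#
# charge: side-chain charge at physiological pH.
# hydropathy: six-way hydropathy partition; cysteine is kept as its own
# class because of its special role in metal coordination.
charge:
  positive: [K, R, H]
  negative: [D, E]
  neutral: [A, C, F, G, I, L, M, N, P, Q, S, T, V, W, Y]
hydropathy:
  strong_hydrophilic: [R, D, E, N, Q, K]
  strong_hydrophobic: [L, I, V, A, M, F]
  weak_amphipathic: [S, T, H, Y, W]
  proline: [P]
  glycine: [G]
  cysteine: [C]
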