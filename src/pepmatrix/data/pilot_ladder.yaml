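# Canonical residue ladder for the 6x6 pilot sparse matrix (version 1).
#
# Hydrophobic levels occupy positions 1,2,5,6,9 (one tuple per matrix row,
# top to bottom): mean Kyte-Doolittle hydropathy decreases monotonically
# 2.94 -> 2.46 -> 2.44 -> 2.06 -> 1.86 -> 1.82.  Note Trp is hydrophilic on
# the Kyte-Doolittle scale (-0.9), so the aromatic-rich top rows use it
# sparingly to keep the gradient monotone.
#
# Charge levels occupy positions 3,4,7,8 (one tuple per matrix column, left
# to right): formal charge at pH 7 decreases +4 -> +3 -> +2 -> 0 -> -1 -> -2.
# Column 4 (K,D,E,R) and column 6 (Q,D,N,E) reproduce the published anchor
# peptides AMKDAMERM and AMQDAMNEM in row 5.
name: pilot-v1
hydrophobic_positions: [1, 2, 5, 6, 9]
charged_positions: [3, 4, 7, 8]
hydrophobic_levels:
  - [W, F, L, I, I]
  - [W, F, L, L, F]
  - [F, L, M, M, A]
  - [F, M, M, A, M]
  - [A, M, A, M, M]
  - [A, A, A, M, A]
charge_levels:
  - [K, R, K, R]
  - [K, R, K, H]
  - [K, R, H, H]
  - [K, D, E, R]
  - [K, D, E, E]
  - [Q, D, N, E]
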