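# srnatarget nearest-neighbor free-energy parameters, 37 C (kcal/mol)
#
# Format: "[section]" headers followed by data lines; "#" starts a comment.
#   [constants]  key = value pairs
#   [stack]      6x6 table. Row = outer pair (5'i,3'j), column = inner pair
#                (i+1, j-1), both written 5'-side nucleotide first.
#                Order: CG GC GU UG AU UA.
#   [hairpin] / [bulge] / [internal]
#                "length value" pairs (loop length = number of unpaired
#                nucleotides; internal length = sum of the two sides).
#                Lengths beyond the last entry extrapolate as
#                value(max) + lxc * ln(L / max).
#
# Values are the published Turner-2004 RNA parameters (stacking free
# energies and loop-length initiation terms); multiloop scoring is the
# affine closing/branch/unpaired model.

[constants]
temperature = 310.15
terminal_AU = 0.50
duplex_init = 0.00
multiloop_closing = 9.30
multiloop_branch = -0.90
multiloop_unpaired = 0.00
lxc = 1.07856
max_loop_span = 30

[stack]
# inner:  CG     GC     GU     UG     AU     UA
CG      -3.30  -2.40  -1.40  -2.10  -2.10  -2.10
GC      -3.40  -3.30  -1.50  -2.50  -2.40  -2.20
GU      -2.50  -2.10  -0.50   1.30  -1.30  -1.40
UG      -1.50  -1.40   0.30  -0.50  -1.00  -0.60
AU      -2.20  -2.10  -0.60  -1.40  -0.90  -1.10
UA      -2.40  -2.10  -1.00  -1.30  -1.30  -0.90

[hairpin]
3 5.40
4 5.60
5 5.70
6 5.40
7 6.00
8 5.50
9 6.40
10 6.50
11 6.60
12 6.70
13 6.80
14 6.90
15 6.90
16 7.00
17 7.10
18 7.10
19 7.20
20 7.20
21 7.30
22 7.30
23 7.40
24 7.40
25 7.50
26 7.50
27 7.50
28 7.60
29 7.60
30 7.70

[bulge]
1 3.80
2 2.80
3 3.20
4 3.60
5 4.00
6 4.40
7 4.60
8 4.70
9 4.80
10 4.90
11 5.00
12 5.10
13 5.20
14 5.30
15 5.40
16 5.40
17 5.50
18 5.50
19 5.60
20 5.70
21 5.70
22 5.80
23 5.80
24 5.80
25 5.90
26 5.90
27 6.00
28 6.00
29 6.00
30 6.10

[internal]
2 1.00
3 1.00
4 1.10
5 2.00
6 2.00
7 2.10
8 2.30
9 2.40
10 2.50
11 2.60
12 2.70
13 2.80
14 2.90
15 2.90
16 3.00
17 3.10
18 3.10
19 3.20
20 3.30
21 3.30
22 3.40
23 3.40
24 3.50
25 3.50
26 3.50
27 3.60
28 3.60
29 3.70
30 3.70
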