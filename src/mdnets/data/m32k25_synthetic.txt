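# Synthetic stand-in for the M32K25 structural alphabet (25 letters).
# NOT the published prototype coordinates: fragments are built on a
# pseudo-bond-angle / pseudo-torsion grid (theta x tau) with 3.8 A
# virtual Ca-Ca bonds, covering the helical-to-extended range.
# Format: '>letter' header followed by four 'x y z' lines (A).
>A
-3.676469 -1.896844 -0.324721
0.123531 -1.896844 -0.324721
-0.009087 1.900841 -0.324721
3.562024 1.892848 0.974164
>B
-2.867545 -1.868596 -0.945808
0.932455 -1.868596 -0.945808
0.799837 1.929089 -0.945808
1.135254 1.808103 2.837425
>C
-1.963126 -1.837013 -0.474711
1.836874 -1.837013 -0.474711
1.704256 1.960672 -0.474711
-1.578004 1.713354 1.424132
>D
-2.007601 -1.838566 0.544566
1.792399 -1.838566 0.544566
1.659781 1.959119 0.544566
-1.444578 1.718013 -1.633697
>E
-2.949613 -1.871462 0.934997
0.850387 -1.871462 0.934997
0.717769 1.926223 0.934997
1.381457 1.816701 -2.804992
>F
-4.140217 -1.870132 -0.317819
-0.340217 -1.870132 -0.317819
0.449848 1.846829 -0.317819
4.030586 1.893435 0.953457
>G
-3.365317 -2.034842 -0.925704
0.434683 -2.034842 -0.925704
1.224747 1.682119 -0.925704
1.705886 2.387565 2.777113
>H
-2.498938 -2.218996 -0.464620
1.301062 -2.218996 -0.464620
2.091126 1.497965 -0.464620
-0.893250 2.940028 1.393860
>I
-2.541543 -2.209940 0.532990
1.258457 -2.209940 0.532990
2.048522 1.507020 0.532990
-0.765436 2.912860 -1.598971
>J
-3.443933 -2.018132 0.915123
0.356067 -2.018132 0.915123
1.146132 1.698829 0.915123
1.941734 2.337434 -2.745369
>K
-4.586623 -1.730282 -0.292035
-0.786623 -1.730282 -0.292035
0.879187 1.685135 -0.292035
4.494058 1.775429 0.876106
>L
-3.932353 -2.049391 -0.850605
-0.132353 -2.049391 -0.850605
1.533458 1.366026 -0.850605
2.531248 2.732755 2.551816
>M
-3.200844 -2.406172 -0.426927
0.599156 -2.406172 -0.426927
2.264966 1.009246 -0.426927
0.336722 3.803097 1.280782
>N
-3.236817 -2.388627 0.489751
0.563183 -2.388627 0.489751
2.228994 1.026791 0.489751
0.444639 3.750462 -1.469252
>O
-3.998730 -2.017016 0.840882
-0.198730 -2.017016 0.840882
1.467080 1.398401 0.840882
2.730381 2.635632 -2.522647
>P
-4.987676 -1.483695 -0.248902
-1.187676 -1.483695 -0.248902
1.254917 1.427274 -0.248902
4.920435 1.540117 0.746707
>Q
-4.512401 -1.882498 -0.724973
-0.712401 -1.882498 -0.724973
1.730192 1.028471 -0.724973
3.494611 2.736525 2.174919
>R
-3.981019 -2.328381 -0.363871
-0.181019 -2.328381 -0.363871
2.261574 0.582588 -0.363871
1.900465 4.074173 1.091613
>S
-4.007150 -2.306454 0.417416
-0.207150 -2.306454 0.417416
2.235443 0.604515 0.417416
1.978858 4.008393 -1.252247
>T
-4.560619 -1.842038 0.716686
-0.760619 -1.842038 0.716686
1.681973 1.068931 0.716686
3.639265 2.615146 -2.150059
>U
-5.317338 -1.144036 -0.190983
-1.517338 -1.144036 -0.190983
1.556926 1.089548 -0.190983
5.277751 1.198524 0.572948
>V
-5.037521 -1.529171 -0.556271
-1.237521 -1.529171 -0.556271
1.836743 0.704413 -0.556271
4.438299 2.353929 1.668813
>W
-4.724671 -1.959772 -0.279198
-0.924671 -1.959772 -0.279198
2.149593 0.273812 -0.279198
3.499749 3.645733 0.837594
>X
-4.740056 -1.938597 0.320283
-0.940056 -1.938597 0.320283
2.134209 0.294987 0.320283
3.545903 3.582208 -0.960848
>Y
-5.065910 -1.490098 0.549913
-1.265910 -1.490098 0.549913
1.808355 0.743486 0.549913
4.523464 2.236710 -1.649738
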