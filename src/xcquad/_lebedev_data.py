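"""Lebedev-Laikov generator parameters (octahedral symmetry classes).

Each entry: algebraic order, list of symmetry classes
(class type, geometric parameters..., weight); weights are
normalized to sum to 1 over the full grid and verified to
integrate all even monomial moments up to the stated order
to machine precision.
"""

LEBEDEV_CLASSES = {
    6: (3, [
        (1, 0.1666666666666667),
    ]),
    14: (5, [
        (1, 0.06666666666666667),
        (3, 0.075),
    ]),
    26: (7, [
        (1, 0.04761904761904762),
        (2, 0.0380952380952381),
        (3, 0.03214285714285714),
    ]),
    38: (9, [
        (1, 0.009523809523809525),
        (3, 0.03214285714285714),
        (5, 0.4597008433809831, 0.02857142857142857),
    ]),
    50: (11, [
        (1, 0.0126984126984127),
        (2, 0.02257495590828924),
        (3, 0.02109375),
        (4, 0.3015113445777636, 0.02017333553791887),
    ]),
    86: (15, [
        (1, 0.01154401154401154),
        (3, 0.01194390908585628),
        (4, 0.3696028464541502, 0.0111105557106034),
        (4, 0.6943540066026664, 0.01187650129453714),
        (5, 0.3742430390903412, 0.01181230374690448),
    ]),
    110: (17, [
        (1, 0.003828270494937162),
        (3, 0.009793737512487513),
        (4, 0.1851156353447362, 0.008211737283191111),
        (4, 0.6904210483822922, 0.009942814891178103),
        (4, 0.3956894730559419, 0.009595471336070962),
        (5, 0.4783690288121502, 0.009694996361663029),
    ]),
    194: (23, [
        (1, 0.001782340447244611),
        (2, 0.005716905949977102),
        (3, 0.005573383178848738),
        (4, 0.6712973442695226, 0.005608704082587997),
        (4, 0.2892465627575439, 0.005158237711805383),
        (4, 0.4446933178717437, 0.005518771467273614),
        (4, 0.1299335447650067, 0.004106777028169394),
        (5, 0.3457702197611283, 0.005051846064614808),
        (6, 0.159041710538353, 0.8360360154824589, 0.005530248916233094),
    ]),
    302: (29, [
        (1, 0.0008545911725128148),
        (3, 0.003599119285025571),
        (4, 0.3515640345570105, 0.003449788424305883),
        (4, 0.6566329410219612, 0.003604822601419882),
        (4, 0.4729054132581005, 0.003576729661743367),
        (4, 0.09618308522614784, 0.002352101413689164),
        (4, 0.2219645236294178, 0.003108953122413675),
        (4, 0.7011766416089545, 0.003650045807677255),
        (5, 0.2644152887060663, 0.002982344963171804),
        (5, 0.5718955891878961, 0.00360082093221646),
        (6, 0.2510034751770465, 0.8000727494073951, 0.003571540554273387),
        (6, 0.1233548532583327, 0.4127724083168531, 0.00339231220500617),
    ]),
    590: (41, [
        (1, 0.0003095121295306187),
        (3, 0.001852379698597489),
        (4, 0.7040954938227469, 0.001871790639277744),
        (4, 0.6807744066455244, 0.001858812585438317),
        (4, 0.6372546939258752, 0.001852028828296213),
        (4, 0.5044419707800358, 0.001846715956151242),
        (4, 0.4215761784010967, 0.001818471778162769),
        (4, 0.3317920736472123, 0.001749564657281154),
        (4, 0.2384736701421887, 0.001617210647254411),
        (4, 0.1459036449157763, 0.001384737234851692),
        (4, 0.06095034115507196, 0.000976433116505105),
        (5, 0.6116843442009876, 0.001857161196774078),
        (5, 0.3964755348199858, 0.001705153996395864),
        (5, 0.1724782009907724, 0.001300321685886048),
        (6, 0.561026380862206, 0.3518280927733519, 0.001842866472905286),
        (6, 0.474239284255198, 0.263471665593795, 0.001802658934377451),
        (6, 0.598412649788538, 0.1816640840360209, 0.00184983056044366),
        (6, 0.3791035407695563, 0.1720795225656878, 0.001713904507106709),
        (6, 0.2778673190586244, 0.08213021581932511, 0.001555213603396808),
        (6, 0.5033564271075117, 0.08999205842074876, 0.001802239128008525),
    ]),
    974: (53, [
        (1, 0.0001438294190527431),
        (3, 0.001125772288287004),
        (4, 0.04292963545341347, 0.0004948029341949241),
        (4, 0.1051426854086404, 0.000735799010912547),
        (4, 0.1750024867623087, 0.0008889132771304384),
        (4, 0.2477653379650257, 0.0009888347838921435),
        (4, 0.3206567123955957, 0.001053299681709471),
        (4, 0.3916520749849983, 0.001092778807014578),
        (4, 0.4590825874187624, 0.001114389394063227),
        (4, 0.5214563888415861, 0.001123724788051555),
        (4, 0.6253170244654199, 0.001125239325243814),
        (4, 0.663792674452317, 0.001126153271815905),
        (4, 0.6910410398498301, 0.001130286931123841),
        (4, 0.705290700745776, 0.001134986534363955),
        (5, 0.123668676265799, 0.0006823367927109931),
        (5, 0.2940777114468387, 0.0009454158160447096),
        (5, 0.4697753849207649, 0.001074429975385679),
        (5, 0.6334563241139567, 0.001129300086569132),
        (6, 0.05974048614181342, 0.2029128752777523, 0.0008436884500901954),
        (6, 0.1375760408473636, 0.4602621942484054, 0.001075255720448885),
        (6, 0.3391016526336286, 0.5030673999662036, 0.001108577236864462),
        (6, 0.127167519143982, 0.2817606422442134, 0.0009566475323783357),
        (6, 0.2693120740413512, 0.4331561291720157, 0.001080663250717391),
        (6, 0.1419786452601918, 0.6256167358580814, 0.001126797131196295),
        (6, 0.06709284600738255, 0.3798395216859157, 0.001022568715358061),
        (6, 0.07057738183256172, 0.551750542142352, 0.001108960267713108),
        (6, 0.2783888477882155, 0.6029619156159187, 0.001122790653435766),
        (6, 0.1979578938917407, 0.3589606329589096, 0.00103240184711746),
        (6, 0.2087307061103274, 0.5348666438135476, 0.001107249382283854),
        (6, 0.4055122137872836, 0.5674997546074373, 0.001121780048519972),
    ]),
}
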