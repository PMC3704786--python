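>nqrA_ref Na+-translocating NADH dehydrogenase subunit NqrA (synthetic stand-in)
IDAAIEYDARSLHPSPKGASYYDIAVVSECALEKCIRDVALRVSAARCPRLPAEVTALIYYAGKLIYLRR
ANSAEIGLGIEILTEPGEKTGHLYEKPGVGGFKMIHLKEGFEAELKLRSRIGYTVLYGETVIKQLDLPVY
PSPVAKKVEFSLKACNPAVLLKITTPVTLQLPAEQISEFKELTERLDSGLSWHKYAINLYALINPVVESR
EAINAAIKKTSRSGPGTYAGRMGFGGAGEIGITRYHPDLLANAKVVQMLDQETSYEWLAAAKNPGMANMK
GGAEHVGGSYQVEQFEGDVG
>nqrB_ref Na+-translocating NADH dehydrogenase subunit NqrB (synthetic stand-in)
PNKQGRLIEYICTLQNIQATNIKDIGTLFLRRSMPDIILATITSRTSLFHRYAKKKGPYDDSKIEISTSA
TTFSTTGGDVRVCFEDMQPDVFSALPQYPIKARTPQGLDPLHRVRDFYLTKSDKGAHCLPKGASHQTAVA
AEIVYQQITDLGGNLKFGKPDPGPFPLAAQSMVTVQQEESVNYLTYRPKSGELLVVLGEDLRGSVGLTEA
PEPEVELGDNKKEIRGFVEHPIRSFIVLAGVLNYGYTLKRQWSELDVLNTSALLPKSNACNDKPGVDFEY
PKFDLSFLLAKDHAHNKRQM
>nqrC_ref Na+-translocating NADH dehydrogenase subunit NqrC (synthetic stand-in)
PILKFLNEKPLKFCSKRNDKHAEFLRMRYPVRTHAGQMYASANCLTSAEQRGDFRSSGLENGHDTSFFNF
IEPYAVLAGTFIEVRAIAAFGPFYLVARNYSGFQETFLVKFENNQAQAPRTVVQQSISNATGVQDPAHRI
NYYKLDTPMPKPTTINAHQDPKLDWGEVINTVAKGGDVVEVLLYAKAVFFSCLLIIFGLGANVVENSVKM
EVKTSEVGDSENVNFQSETTVFLAFDGERRSPTEPEARIPERLQHNDVVSVFLAPDPDWALSVLLTRVLD
QEVLGFDKMDEHMNLSTHHF
>nqrD_ref Na+-translocating NADH dehydrogenase subunit NqrD (synthetic stand-in)
QEMDQYFTIAFSTSEVKLEAERWATRASAVISKVRYCDILFGIQPVSPYALHTNPPLMVLWGDSEANAIF
EREKRSLADKNLGDAGRKRHFEVSGMEYLPESIASRTRHMGFTVLILFLGQSRELNVKFLETATLDFKRV
VGHIILFRQFSLIQIAIDGDVPIPVGPIALQSATIEELQMRKHLKDLWLKMDVTLKAHAVMLSRMIWAST
NLESVLCGKEYTIERSGVDKAASLNENPPHLAGLLNKSMALMRNNGDGWNQAVKSGIERSPSDLDFFISV
SIVMQYLNSMSVVQVSDNQV
>nqrE_ref Na+-translocating NADH dehydrogenase subunit NqrE (synthetic stand-in)
TTDERNSVKNVKMSLVILNELKQKFGTILTLLIECQLEASKWGEGSHFYPICIYVQKAGAEDDNFTTSIE
ECLRRAARDLIGHNDIRKFWMLSFIKSKVALWSLLQLNASFEKAESAYFQRGLLDKLLIQRTFRSALTSS
ISASLEDSPRNQSLSRMARWTRGNHGGTEVANGMLNYIIFAQLGGYGSRIYMFQRDELVGDDKNRQRRQT
ATLDLPTFSARVVARQGAIDQYRCREIAAGGIIFCGAVGKGTVDRLMRGKGNELLGDNTVNDANKYHHPA
LYFYLPTWLALAIEKQITLE
>nqrF_ref Na+-translocating NADH dehydrogenase subunit NqrF (synthetic stand-in)
VHAYGVGHQKEKIEVGPRSEGKKPIDEFALRKRLKVERDIRCPTIPLWAATTVALSKSSDETPDTTNNGE
SFCSYLDNERFTVIVGAPIEFPTRLLYASEGTGSNLELLVTVGGVRVVKAPRMLVVLHLKEAPVNLISLD
AVGITHALALPQYNDFGIALGTLLETTKSGKTELKDYRFKLHKQRNINKSNDAYHQSNGKYYYAGTINRR
FTRKNLILQEQRLSGCMGFAKLGREQHWTAPIGVKNKSLWFERVHETSYNGISLRKNNFRNLKMNPIIRK
QEAYGCDNHFLNLGLRDADL
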