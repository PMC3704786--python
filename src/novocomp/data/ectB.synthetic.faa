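>ectB_ref1 ectB designated reference (synthetic stand-in)
TIDTPMVREAPCDPFTLQREETYRILSTVCLFAQIAFLEYGGSQIDIYRQEQLERWATKEVLIFIVVEDW
DRGSGAEVIWRKLLIAESMDDVKKIKMVVRDVDRPQYWHNYVLEKMLEQFQRRFYEIKSVNAFISAHDFG
ANSKVGFWTVKLLEADEYAISPYFKSQEGPEKEAFRVVQDEGYRGIITNNLMYTGPVYETKQSLRHFLGE
KQEEIVHDLQVFKLPDVVAFLFDAHEYLETAQTLASNSRSEAFDGEFIGTPFRDAPGGAYNLASMRSIVL
IPASVAPVQYPSLNFQRGRMSGKNPYMFTEQGGLGEFERPMELQDGLPAVQNAPKTGLAGTGASELAQCT
RFDLEYELAGNGRIIQVMTRHGPHDSRASPRYPMHNSFNIADITISKPKAIVGLIQGSREEVLPVTFAPD
>ectB_ref2 ectB homolog (synthetic stand-in)
TVDTPMSREYHVCSFTYRTEESHYIVKTAIPYAQIAFSENGGIQIAIYRQEALLQYLTKRVLVFIVIEEF
DNGSGGEVSYKKCLFAESMSDSLKTTMVSRDVDRPQWWHNYHLQKMLMQHLRRYYSIKSVNAHISANDIM
ANSFVGLYTVKLLEADAYDYDTQFKSQEGPEKEAFRQVQDETYEGIVTDNFMYNSDIYETLRSLRDYIGE
KQEEIVEQMQVFKLSSVDAFLLSKQERSETEQTLESNWRSEAFDGEFIGTPFSDRPWGYENLFPMRSIVL
IPASTAPCKYPHLNDWWDRAAGLNSYCFIEQGGLGEFRRYMKKQPGIIAPQMAPKVGAAGGGASELHNST
RDELEYELTIKMRIIQVMTRHGPSDSRCSPRYPMPRSFNIADIMICKPGAIYGLITDAQHEVLPAQFAPM
>ectB_ref3 ectB homolog (synthetic stand-in)
TIDPPWYRQWACDPFTLDRDETYPLLSTVHCKACLRLLEYGGNQIAIYRIEQLERFGTKEVLIWMVTEDW
DRISGAEMIAFKALVTESWDQVMTVKMVVRDVDRIQQWHHHIKENMLEMAQRRMFETKQVQAFISEGNFT
ANSKVNFSTVKLLSADEYAISPHFESQEGSEKEAFRVVKTEGWRGLITNELMPTGMPYNTPQSLRYDLSE
KTEEILHDLQVFYLPQVVNFVYDAHEWSETAQTLVYDSRIKAFDGENIGTPFTDCPSSAYNWAKMHVYVS
CPASVAPVQYPSLNKQRPRTSGKMPYAIREPGRLGEFERPMWLLLGLPWVQDAGKTWHGATGASETSQCT
RFDLEYELAGIGRIIQVMTRHGPYDVRACPRYQLYYSFFFADISVSMPKAIVGDIMFSGEEEIPITFAPT
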