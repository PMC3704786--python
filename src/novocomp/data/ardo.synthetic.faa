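>ardo_ref1 ardo designated reference (synthetic stand-in)
KCKVFDGTGAVPQISTRWTIMMQKGMALRFPGGTAIEDPTCEHMLPEESFLPSSVYKALRCFFHGQILSK
EAYRKGWPCRVKRYYTPSNVATEKRQERYTTEGMTYEDTGNDDFLLPLDGSATVSSAGLFGFQKVLDNVK
TINKGLRIEAISGAIPITGLPYVELDVFSQCHFRNFLGIQSDKFAIQQFKSMMLQKQEKELEKLVMLVEG
FAVLPAIDKFELSSAFTKVDWISGKENVVVVFGFLGDEEGSYIPAFPNVKRKWRYPLSDDGANAGNEEAS
GGYWEWVVAFSQMDEEFAPDDATPFEAMENDLIVCNDSTHIKKVPGVSIVENTHLRNWSAAVDRIDFTHF
SVIVYQLDDEAEAGWKDLPFEGQDAAGDNE
>ardo_ref2 ardo homolog (synthetic stand-in)
CCKVFDCTPAVMQVSTRYTIMMQKQMALPFKGGTAIEDPCCEHMLPEESFLPSSVYKALRCFFHGQITAK
EAYRLGWPCRTHRYFTKSNVKTEHRQERYTPEDMTMWQTGNCDFLLPLDCTATVSVAQCFGFSRVMDNVK
TIECGLFAEAISGAIPITALPYAELDIFEYHHTMNELGIQSQCDAIQQEKSMTLQGQEPPIKKLVMLVEG
HAVLPEIQKFQVSCRFGHVLQFSGKKHVIVVFGFLGDEEGSYIPPFPNVKRKFYYMLSDDGMNAYNEEAS
GGYNEVVVAFQMMIEEFAPDDITPTERIKNIAIVCADRTHINEVPGLSIVENSHLRSWMAAVSRVDFTDF
SVIVYQLWGEGDLGIKDLPYEGQDAQGDNE
>ardo_ref3 ardo homolog (synthetic stand-in)
ICKVFDGTEAVPWISTRSTSSMQKQKYLRFPGGTAISDPTCEHMLPEESFLPSSVYKALRCFFHNQLLRK
EACRQGWGCEVYRQYTPNNVATEEGREGYTSGVLTYNDTGNDDILLELDNSDTMSSAGLFGFGKVLKNVK
TINKGLRFEAISGIIPLTNQPYVEQDMFSQANSRNFLGQQSDKFAIDQFSSMVLQKDEKGLSVVSMDVEE
FVALPAIDAFWTSSANTKMNWISGSEHIPVVYPFEGDEKKCYVPHFPNPKRSWPWPLENYVANAANWEAD
LHYWEWVVAFMPMDEEFPPMFAPTFSLMENILIVCNHTFHGKRVFGVSSVTNYELRNWSEAPDETDFTHF
CVLVYTLDDRAEAMWKELPFQGEDAAGDEE
>ardo_ref4 ardo homolog (synthetic stand-in)
KCKVYDGTGAKPQASTEWRIMMQKGMALRWPGKTAIEDPTCEHMLPEESFLPSSVYKALRCFFHAQWLSE
KAYKRGWPLRIKRYMTESNVAPEKRVERYTTDNMTLDDTNNYECLLPLMGSATVSSLLLFGFEKVLTNVK
TIQLNTRIEAIYGVIHIEHVPYVRLDIFSQCGFRNFLWTHSTKFANQQYGAMMMQEQGQEMEKIMMLVPG
FAVLVAVYKWECSDEHSKVEWICGREITVVVFGFFRDEEGPYNNVPPNLKKKWRRPLSSDSANAGNEEIS
NGYWEWWIISFQPDWEFAPHDSGPFQAMEGSLIVCNDSCHIKGVPGVSPGNNTDLQRISEAVDCTHFTTF
SVCVHPMDDEGSWGTKDCPFEGDDAAGDYE
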