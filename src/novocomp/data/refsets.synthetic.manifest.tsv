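id	set	annotation
luxI_ref1	luxI	luxI designated reference (synthetic stand-in)
luxI_ref2	luxI	luxI homolog (synthetic stand-in)
luxI_ref3	luxI	luxI homolog (synthetic stand-in)
luxI_ref4	luxI	luxI homolog (synthetic stand-in)
luxI_ref5	luxI	luxI homolog (synthetic stand-in)
luxI_ref6	luxI	luxI homolog (synthetic stand-in)
luxR_ref1	luxR	luxR designated reference (synthetic stand-in)
luxR_ref2	luxR	luxR homolog (synthetic stand-in)
luxR_ref3	luxR	luxR homolog (synthetic stand-in)
luxR_ref4	luxR	luxR homolog (synthetic stand-in)
luxR_ref5	luxR	luxR homolog (synthetic stand-in)
nqrA_ref	nqr	Na+-translocating NADH dehydrogenase subunit NqrA (synthetic stand-in)
nqrB_ref	nqr	Na+-translocating NADH dehydrogenase subunit NqrB (synthetic stand-in)
nqrC_ref	nqr	Na+-translocating NADH dehydrogenase subunit NqrC (synthetic stand-in)
nqrD_ref	nqr	Na+-translocating NADH dehydrogenase subunit NqrD (synthetic stand-in)
nqrE_ref	nqr	Na+-translocating NADH dehydrogenase subunit NqrE (synthetic stand-in)
nqrF_ref	nqr	Na+-translocating NADH dehydrogenase subunit NqrF (synthetic stand-in)
ardo_ref1	ardo	ardo designated reference (synthetic stand-in)
ardo_ref2	ardo	ardo homolog (synthetic stand-in)
ardo_ref3	ardo	ardo homolog (synthetic stand-in)
ardo_ref4	ardo	ardo homolog (synthetic stand-in)
ectA_ref1	ectA	ectA designated reference (synthetic stand-in)
ectA_ref2	ectA	ectA homolog (synthetic stand-in)
ectA_ref3	ectA	ectA homolog (synthetic stand-in)
ectB_ref1	ectB	ectB designated reference (synthetic stand-in)
ectB_ref2	ectB	ectB homolog (synthetic stand-in)
ectB_ref3	ectB	ectB homolog (synthetic stand-in)
ectC_ref1	ectC	ectC designated reference (synthetic stand-in)
ectC_ref2	ectC	ectC homolog (synthetic stand-in)
ectC_ref3	ectC	ectC homolog (synthetic stand-in)
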